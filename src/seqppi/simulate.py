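"""Synthetic proteomes and pair sets with a planted interaction signal.

Real interaction benchmarks pair a curated positive set with sampled
non-interacting pairs.  This generator emulates that structure without
any download: random amino-acid sequences, and a tunable "interaction"
signal planted as complementary motif pairs — each positive pair
receives (with probability ``p_signal``) motif alpha written into
protein A and its partner motif beta into protein B, chosen from a
small pool of motif pairs.  Negative pairs never receive a coordinated
insertion.

Motif pairs model electrostatic interface complementarity: alpha is an
acidic low-complexity patch (residues drawn from D/E) and beta the
matching basic patch (K/R), the pattern of salt-bridge-mediated
interfaces such as E/K coiled coils.  Charged homorepeat patches are
common in real linear interaction motifs, and — unlike motifs of
uniformly random composition, whose triads are indistinguishable from
background in the reduced 7-group alphabet — they are visible to the
conjoint-triad and local-descriptor blocks, which is the point of the
planted signal.  The implants are verifiable by substring search, and
signal strength is controlled by ``p_signal``, the motif length and
the pool size.

Every pair uses its own two proteins (the generator requires a
proteome of at least 2*(n_pos+n_neg) sequences), so an implant in one
pair can never leak into another.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import AMINO_ACIDS
from .io import PAIR_COLUMNS, ProteinRecord


@dataclass(frozen=True)
class SignalSpec:
    """Parameters of the planted-signal generator.

    n_motif_pairs
        Size of the pool of complementary motif pairs (default 3).
    motif_length
        Length of each motif in residues (default 6).
    p_signal
        Probability that a positive pair receives a motif implant
        (default 1.0; 0 gives a signal-free null dataset).
    background
        Optional 20-vector of amino-acid frequencies in the order
        ACDEFGHIKLMNPQRSTVWY; None means uniform.
    length_range
        Inclusive (min, max) sequence length; the default floor of 50
        residues matches the benchmark length filter.
    motif_alphabet_a, motif_alphabet_b
        Residue alphabets the alpha (protein A) and beta (protein B)
        motifs are drawn from.  Defaults D/E vs K/R: charge-
        complementary acidic/basic patches.
    """

    n_motif_pairs: int = 3
    motif_length: int = 6
    p_signal: float = 1.0
    background: Sequence[float] | None = None
    length_range: tuple[int, int] = (50, 400)
    motif_alphabet_a: str = "DE"
    motif_alphabet_b: str = "KR"

    def __post_init__(self):
        if not 0.0 <= self.p_signal <= 1.0:
            raise ValueError("p_signal must lie in [0, 1]")
        if self.n_motif_pairs < 1 or self.motif_length < 1:
            raise ValueError("n_motif_pairs and motif_length must be >= 1")
        lo, hi = self.length_range
        if lo > hi or lo < self.motif_length:
            raise ValueError(
                f"invalid length range {self.length_range}: lengths must be "
                f">= motif_length={self.motif_length}"
            )
        if self.background is not None:
            p = np.asarray(self.background, dtype=float)
            if p.shape != (20,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError("background must be 20 non-negative frequencies summing to 1")
        for alphabet in (self.motif_alphabet_a, self.motif_alphabet_b):
            if not alphabet or not set(alphabet) <= set(AMINO_ACIDS):
                raise ValueError(f"invalid motif alphabet {alphabet!r}")

    def background_probs(self) -> np.ndarray:
        if self.background is None:
            return np.full(20, 1 / 20)
        return np.asarray(self.background, dtype=float)


def _as_rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def _random_sequence(length: int, probs: np.ndarray, rng: np.random.Generator) -> str:
    letters = rng.choice(np.array(list(AMINO_ACIDS)), size=length, p=probs)
    return "".join(letters)


def gen_proteome(n: int, spec: SignalSpec | None = None, rng=None) -> dict[str, ProteinRecord]:
    """Generate n i.i.d. background sequences with uniform random lengths."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or SignalSpec()
    rng = _as_rng(rng)
    lo, hi = spec.length_range
    probs = spec.background_probs()
    width = len(str(n))
    proteome = {}
    for i in range(n):
        pid = f"P{i:0{width}d}"
        length = int(rng.integers(lo, hi + 1))
        proteome[pid] = ProteinRecord(pid, _random_sequence(length, probs, rng))
    return proteome


def _implant(seq: str, motif: str, rng: np.random.Generator) -> str:
    """Overwrite a random window of the sequence with the motif
    (insertion by replacement keeps the length, hence the length floor)."""
    pos = int(rng.integers(0, len(seq) - len(motif) + 1))
    return seq[:pos] + motif + seq[pos + len(motif) :]


def gen_pairs(
    proteome: Mapping[str, ProteinRecord],
    n_pos: int,
    n_neg: int,
    spec: SignalSpec | None = None,
    rng=None,
) -> tuple[pd.DataFrame, dict[str, ProteinRecord], list[tuple[str, str]]]:
    """Draw labeled pairs and plant the interaction signal.

    Returns ``(pairs, proteome, motifs)``: the pair table (positives
    first, order as generated), the modified proteome (copies with
    motifs implanted), and the pool of (alpha, beta) motif pairs so the
    implants can be verified by substring search.
    """
    spec = spec or SignalSpec()
    rng = _as_rng(rng)
    ids = list(proteome)
    need = 2 * (n_pos + n_neg)
    if len(ids) < need:
        raise ValueError(
            f"proteome has {len(ids)} proteins; {need} needed for "
            f"{n_pos}+{n_neg} disjoint pairs"
        )
    def _motif(alphabet: str) -> str:
        return "".join(rng.choice(list(alphabet), size=spec.motif_length))

    motifs = [
        (_motif(spec.motif_alphabet_a), _motif(spec.motif_alphabet_b))
        for _ in range(spec.n_motif_pairs)
    ]
    order = rng.permutation(len(ids))
    out = dict(proteome)
    rows = []
    cursor = 0
    for label, count in ((1, n_pos), (0, n_neg)):
        for _ in range(count):
            id_a, id_b = ids[order[cursor]], ids[order[cursor + 1]]
            cursor += 2
            if label == 1 and rng.random() < spec.p_signal:
                alpha, beta = motifs[int(rng.integers(spec.n_motif_pairs))]
                out[id_a] = ProteinRecord(id_a, _implant(out[id_a].sequence, alpha, rng))
                out[id_b] = ProteinRecord(id_b, _implant(out[id_b].sequence, beta, rng))
            rows.append((id_a, id_b, label))
    pairs = pd.DataFrame(rows, columns=list(PAIR_COLUMNS))
    return pairs, out, motifs
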