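"""Sequence descriptor encoders for protein-pair classification.

A protein pair is represented by four descriptor families computed on
each member of the pair and concatenated into a single 2666-dimensional
vector:

* **AC** — auto covariance of six physicochemical property profiles at
  lags 1..``lg`` (default 30): 180 values per protein.
* **CT** — conjoint-triad frequencies over a reduced 7-letter alphabet:
  7^3 = 343 values per protein.
* **LD** — local descriptors: composition/transition/distribution (CTD)
  statistics over 10 overlapping sequence regions, 63 per region:
  630 values per protein.
* **MAC** — Moran autocorrelation of the same property profiles at
  distances 1..``dmax`` (default 30): 180 values per protein.

The physicochemical table (hydrophobicity, side-chain volume, polarity,
polarizability, solvent-accessible surface area, net charge index) and
the seven-group partition of the amino acids ship as plain-text data
files with the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

PROPERTY_NAMES = (
    "hydrophobicity",
    "side_chain_volume",
    "polarity",
    "polarizability",
    "sasa",
    "net_charge_index",
)

N_PROPERTIES = 6
N_GROUPS = 7
CT_LENGTH = N_GROUPS**3  # 343
REGION_NAMES = tuple("ABCDEFGHIJ")
CTD_LENGTH = 7 + 21 + 35  # 63 per region
LD_LENGTH = len(REGION_NAMES) * CTD_LENGTH  # 630


def _read_packaged_tsv(name: str) -> pd.DataFrame:
    with resources.files("seqppi.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", index_col=0)


@lru_cache(maxsize=None)
def load_property_table(standardized: bool = True) -> pd.DataFrame:
    """The 20x6 physicochemical property table.

    With ``standardized=True`` (default) each property column is scaled
    to zero mean and unit standard deviation over the 20 amino acids,
    which is the form the AC and MAC encoders consume.
    """
    table = _read_packaged_tsv("physicochemical_properties.tsv")
    table = table.loc[list(AMINO_ACIDS), list(PROPERTY_NAMES)].astype(float)
    if standardized:
        table = standardize_table(table)
    return table


def standardize_table(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each property column to mean 0 / SD 1 over the 20 amino acids.

    The SD is the population standard deviation (ddof=0) over the 20
    rows.  A zero-variance column cannot be standardized and raises.
    """
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = list(table.columns[sd == 0])
        raise ValueError(f"zero-variance property column(s): {bad}")
    return (table - mean) / sd


@lru_cache(maxsize=None)
def load_group_map() -> dict[str, int]:
    """Letter -> group index (1..7) for the seven-class reduced alphabet."""
    table = _read_packaged_tsv("seven_groups.tsv")
    return {aa: int(g) for aa, g in table["group"].items()}


@dataclass(frozen=True)
class EncoderConfig:
    """Tunable encoder settings.

    lg
        Maximum auto-covariance lag (AC block width = 6*lg).
    dmax
        Maximum Moran autocorrelation distance (MAC width = 6*dmax).
    ct_relative
        If True (default) conjoint-triad counts are divided by the
        number of windows (L-2) so sequences of different length are
        comparable; if False raw counts are kept.
    """

    lg: int = 30
    dmax: int = 30
    ct_relative: bool = True

    def __post_init__(self):
        if self.lg < 1:
            raise ValueError("lg must be >= 1")
        if self.dmax < 1:
            raise ValueError("dmax must be >= 1")

    @property
    def protein_length(self) -> int:
        return 6 * self.lg + CT_LENGTH + LD_LENGTH + 6 * self.dmax

    @property
    def pair_length(self) -> int:
        return 2 * self.protein_length


def pair_block_layout(config: EncoderConfig | None = None) -> list[tuple[str, int]]:
    """Named block layout of the pair vector, in order."""
    cfg = config or EncoderConfig()
    ac, mac = 6 * cfg.lg, 6 * cfg.dmax
    return [
        ("AC_A", ac),
        ("AC_B", ac),
        ("CT_A", CT_LENGTH),
        ("CT_B", CT_LENGTH),
        ("LD_A", LD_LENGTH),
        ("LD_B", LD_LENGTH),
        ("MAC_A", mac),
        ("MAC_B", mac),
    ]


def property_profile(seq: str, table: pd.DataFrame | None = None) -> np.ndarray:
    """Translate a sequence into its (L, 6) property-value profile."""
    if table is None:
        table = load_property_table()
    values = table.to_numpy()
    try:
        idx = np.fromiter((_AA_INDEX[c] for c in seq), dtype=np.intp, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"unknown residue letter {exc.args[0]!r}") from None
    return values[idx]


def encode_ac(seq: str, table: pd.DataFrame | None = None, lg: int = 30) -> np.ndarray:
    """Auto covariance of the six property profiles at lags 1..lg.

    Entry (j, lag) is the lag-autocovariance of property j along the
    sequence, computed against the sequence mean of that property and
    divided by (L - lag).  Ordering is property-major: the 6*lg output
    places all lags of property 1 first, then property 2, etc.
    """
    L = len(seq)
    if L <= lg:
        raise ValueError(f"sequence length {L} must exceed lg={lg}")
    P = property_profile(seq, table)
    dev = P - P.mean(axis=0)
    dev[:, P.max(axis=0) == P.min(axis=0)] = 0.0  # constant profile: exactly zero
    out = np.empty((N_PROPERTIES, lg))
    for lag in range(1, lg + 1):
        out[:, lag - 1] = (dev[:-lag] * dev[lag:]).sum(axis=0) / (L - lag)
    return out.ravel()


def encode_mac(seq: str, table: pd.DataFrame | None = None, dmax: int = 30) -> np.ndarray:
    """Moran autocorrelation of the property profiles at distances 1..dmax.

    Entry (j, d) is the mean lag-d product of centered property-j values
    divided by the overall (population) variance of that property along
    the sequence; a zero-variance profile yields 0 by convention.
    Ordering matches :func:`encode_ac` (property-major).
    """
    L = len(seq)
    if L <= dmax:
        raise ValueError(f"sequence length {L} must exceed dmax={dmax}")
    P = property_profile(seq, table)
    dev = P - P.mean(axis=0)
    dev[:, P.max(axis=0) == P.min(axis=0)] = 0.0  # constant profile: exactly zero
    var = (dev**2).mean(axis=0)
    out = np.zeros((N_PROPERTIES, dmax))
    nz = var > 0
    for d in range(1, dmax + 1):
        num = (dev[:-d] * dev[d:]).sum(axis=0) / (L - d)
        out[nz, d - 1] = num[nz] / var[nz]
    return out.ravel()


def _group_indices(seq: str, groups: Mapping[str, int] | None = None) -> np.ndarray:
    if groups is None:
        groups = load_group_map()
    try:
        return np.fromiter((groups[c] - 1 for c in seq), dtype=np.intp, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"unknown residue letter {exc.args[0]!r}") from None


def encode_ct(
    seq: str,
    groups: Mapping[str, int] | None = None,
    relative: bool = True,
) -> np.ndarray:
    """Conjoint-triad frequencies over the 7-group alphabet (343 values).

    Every window of three consecutive residues is mapped to a triad
    (g1, g2, g3); entry g1*49 + g2*7 + g3 (0-based groups) counts its
    occurrences, divided by the number of windows (L-2) when
    ``relative`` is set.
    """
    L = len(seq)
    if L < 3:
        raise ValueError(f"sequence length {L} must be >= 3 for conjoint triads")
    g = _group_indices(seq, groups)
    triad = g[:-2] * 49 + g[1:-1] * 7 + g[2:]
    counts = np.bincount(triad, minlength=CT_LENGTH).astype(float)
    if relative:
        counts /= L - 2
    return counts


def split_regions(seq: str) -> dict[str, str]:
    """Split a sequence into the 10 overlapping local regions A..J.

    Using 1-based inclusive positions on a sequence of length L:
    A..D are the four quarters with boundaries at floor(L/4),
    floor(L/2), floor(3L/4) (so A..D partition the sequence exactly);
    E and F are the two halves; G is the central 50 %
    (floor(L/4)+1 .. floor(L/4)+ceil(L/2)); H is the first 75 %
    (1 .. ceil(3L/4)); I the final 75 %; and J the central 75 %
    (floor(L/8)+1 .. floor(L/8)+ceil(3L/4)).
    """
    L = len(seq)
    if L < 4:
        raise ValueError(f"sequence length {L} too short to form non-empty quarters")
    q1, q2, q3 = L // 4, L // 2, (3 * L) // 4
    half = math.ceil(L / 2)
    three_q = math.ceil(3 * L / 4)
    eighth = L // 8
    return {
        "A": seq[:q1],
        "B": seq[q1:q2],
        "C": seq[q2:q3],
        "D": seq[q3:],
        "E": seq[:q2],
        "F": seq[q2:],
        "G": seq[q1 : q1 + half],
        "H": seq[:three_q],
        "I": seq[L - three_q :],
        "J": seq[eighth : eighth + three_q],
    }


_TRANSITION_PAIRS = [(r, s) for r in range(N_GROUPS) for s in range(r + 1, N_GROUPS)]


def encode_ctd_region(region: str, groups: Mapping[str, int] | None = None) -> np.ndarray:
    """Composition/Transition/Distribution statistics of one region (63 values).

    * Composition: 7 per-group residue percentages (sum to 100).
    * Transition: for each of the 21 unordered group pairs (r, s), the
      percentage of adjacent positions where an r-residue neighbours an
      s-residue (in either order), out of len-1 adjacencies.
    * Distribution: for each group, the positions (as % of region
      length) of its first residue and of the residues at the 25/50/75/
      100 % marks of the group's occurrence list (the k%-th residue is
      occurrence number ceil(k/100 * n_g)); absent groups give 5 zeros.
    """
    n = len(region)
    if n < 1:
        raise ValueError("empty region")
    g = _group_indices(region, groups)

    comp = 100.0 * np.bincount(g, minlength=N_GROUPS) / n

    trans = np.zeros(len(_TRANSITION_PAIRS))
    if n > 1:
        a, b = g[:-1], g[1:]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        diff = lo != hi
        pair_idx = {p: i for i, p in enumerate(_TRANSITION_PAIRS)}
        for r, s in zip(lo[diff], hi[diff]):
            trans[pair_idx[(r, s)]] += 1
        trans *= 100.0 / (n - 1)

    dist = np.zeros((N_GROUPS, 5))
    for k in range(N_GROUPS):
        pos = np.flatnonzero(g == k) + 1  # 1-based
        if pos.size == 0:
            continue
        n_g = pos.size
        marks = [1] + [math.ceil(q / 100 * n_g) for q in (25, 50, 75, 100)]
        dist[k] = [100.0 * pos[m - 1] / n for m in marks]

    return np.concatenate([comp, trans, dist.ravel()])


def encode_ld(seq: str, groups: Mapping[str, int] | None = None) -> np.ndarray:
    """Local descriptors: 63 CTD values per region A..J, 630 in total."""
    if groups is None:
        groups = load_group_map()
    regions = split_regions(seq)
    return np.concatenate([encode_ctd_region(regions[r], groups) for r in REGION_NAMES])


def encode_protein(seq: str, config: EncoderConfig | None = None) -> np.ndarray:
    """All four descriptor blocks of one protein: [AC | CT | LD | MAC]."""
    cfg = config or EncoderConfig()
    table = load_property_table()
    groups = load_group_map()
    return np.concatenate(
        [
            encode_ac(seq, table, cfg.lg),
            encode_ct(seq, groups, cfg.ct_relative),
            encode_ld(seq, groups),
            encode_mac(seq, table, cfg.dmax),
        ]
    )


def _assemble_pair(pa: np.ndarray, pb: np.ndarray, cfg: EncoderConfig) -> np.ndarray:
    ac = 6 * cfg.lg
    ct_end = ac + CT_LENGTH
    ld_end = ct_end + LD_LENGTH
    return np.concatenate(
        [
            pa[:ac],
            pb[:ac],
            pa[ac:ct_end],
            pb[ac:ct_end],
            pa[ct_end:ld_end],
            pb[ct_end:ld_end],
            pa[ld_end:],
            pb[ld_end:],
        ]
    )


def encode_pair(seq_a: str, seq_b: str, config: EncoderConfig | None = None) -> np.ndarray:
    """Encode a protein pair into the concatenated descriptor vector.

    Block order is AC_A, AC_B, CT_A, CT_B, LD_A, LD_B, MAC_A, MAC_B;
    with default settings the total length is 2666.
    """
    cfg = config or EncoderConfig()
    return _assemble_pair(encode_protein(seq_a, cfg), encode_protein(seq_b, cfg), cfg)


def encode_pairs(
    proteome: Mapping[str, "object"],
    pairs: pd.DataFrame,
    config: EncoderConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode every pair in a pair table.

    Each protein is encoded once and cached, so proteins appearing in
    many pairs cost a single pass.  Returns ``(X, y)`` where X is
    (n_pairs, pair_length) and y the integer label vector.
    """
    cfg = config or EncoderConfig()
    cache: dict[str, np.ndarray] = {}

    def _enc(pid: str) -> np.ndarray:
        if pid not in cache:
            cache[pid] = encode_protein(proteome[pid].sequence, cfg)
        return cache[pid]

    X = np.empty((len(pairs), cfg.pair_length))
    for i, (a, b) in enumerate(zip(pairs["id_a"], pairs["id_b"])):
        X[i] = _assemble_pair(_enc(a), _enc(b), cfg)
    return X, pairs["label"].to_numpy(dtype=int)


class PairEncoder(TransformerMixin, BaseEstimator):
    """Transformer turning (seq_a, seq_b) string pairs into feature rows.

    Stateless (fit is a no-op); exists so the encoding step composes
    with sklearn pipelines.
    """

    def __init__(self, lg: int = 30, dmax: int = 30, ct_relative: bool = True):
        self.lg = lg
        self.dmax = dmax
        self.ct_relative = ct_relative

    def _config(self) -> EncoderConfig:
        return EncoderConfig(lg=self.lg, dmax=self.dmax, ct_relative=self.ct_relative)

    def fit(self, X: Iterable[Sequence[str]], y=None):
        self._config()  # validates parameters
        return self

    def transform(self, X: Iterable[Sequence[str]]) -> np.ndarray:
        cfg = self._config()
        cache: dict[str, np.ndarray] = {}

        def _enc(seq: str) -> np.ndarray:
            if seq not in cache:
                cache[seq] = encode_protein(seq, cfg)
            return cache[seq]

        rows = [_assemble_pair(_enc(a), _enc(b), cfg) for a, b in X]
        return np.vstack(rows) if rows else np.empty((0, cfg.pair_length))
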