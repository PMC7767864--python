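"""Anthocyanidin composition: categories, dominance, PCA, combination tallies.

Floral anthocyanins split into two biosynthetic families: the common
3-hydroxyanthocyanidins (pelargonidin, cyanidin, peonidin, malvidin,
delphinidin) and the rare 3-deoxyanthocyanidins (apigenidin,
luteolinidin), which lack the 3-OH group and yield only orange/red hues.
Samples are classified by the relative share of each family:

* ``DEO90`` / ``HYD90`` — more than 90% deoxy (resp. hydroxy) pigment;
* ``DEO_HYD`` — both families between 10 and 90%;
* ``NONE`` — no anthocyanins detected;

plus a coarser >50% dominance split (``DEO_dominant`` / ``HYD_dominant``)
used for group comparisons. Composition structure is summarized by a PCA
of four composite variables (PEL, CYA+PEO, DEL+MAL, DEO).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HYDROXY_ANTHOCYANIDINS = ("pelargonidin", "cyanidin", "peonidin", "malvidin", "delphinidin")
DEOXY_ANTHOCYANIDINS = ("apigenidin", "luteolinidin", "unknown_deoxy")
#: the unassigned anthocyanin; counts toward hydroxy by default (configurable)
UNKNOWN = "unknown"
ALL_ANTHOCYANIDINS = HYDROXY_ANTHOCYANIDINS + DEOXY_ANTHOCYANIDINS + (UNKNOWN,)

DEO90, HYD90, DEO_HYD, NONE = "DEO90", "HYD90", "DEO_HYD", "NONE"
DEO_DOMINANT, HYD_DOMINANT, NO_DOMINANCE = "DEO_dominant", "HYD_dominant", "none"


@dataclass
class PigmentComposition:
    """Relative anthocyanidin percentages for one sample.

    Percentages are relative to total anthocyanin content and must sum to
    ~100 (or 0 for anthocyanin-free samples). `unknown_to_deoxy` controls
    which family the unassigned pigment counts toward.
    """

    sample_id: str
    percentages: dict[str, float] = field(default_factory=dict)
    unknown_to_deoxy: bool = False

    def __post_init__(self) -> None:
        unknown_keys = set(self.percentages) - set(ALL_ANTHOCYANIDINS)
        if unknown_keys:
            raise ValueError(f"unrecognized anthocyanidin(s): {sorted(unknown_keys)}")
        for name, pct in self.percentages.items():
            if pct < 0:
                raise ValueError(f"negative percentage for {name}: {pct}")
        total = self.total
        if total != 0 and not 99.9 <= total <= 100.1:
            raise ValueError(f"percentages sum to {total}, expected ~100 or 0")

    def get(self, name: str) -> float:
        return float(self.percentages.get(name, 0.0))

    @property
    def total(self) -> float:
        return float(sum(self.percentages.values()))

    @property
    def deoxy_share(self) -> float:
        share = sum(self.get(n) for n in DEOXY_ANTHOCYANIDINS)
        if self.unknown_to_deoxy:
            share += self.get(UNKNOWN)
        return float(share)

    @property
    def hydroxy_share(self) -> float:
        return float(self.total - self.deoxy_share)

    @property
    def present(self) -> frozenset[str]:
        """Anthocyanidin types detected above 0%."""
        return frozenset(n for n, p in self.percentages.items() if p > 0)


def categorize_sample(c: PigmentComposition) -> str:
    """Four-way pigment category: NONE, DEO90, HYD90 or DEO_HYD."""
    if c.total == 0:
        return NONE
    if c.deoxy_share > 90.0:
        return DEO90
    if c.hydroxy_share > 90.0:
        return HYD90
    return DEO_HYD


def classify_dominance(c: PigmentComposition) -> str:
    """>50% dominance split; an exact 50/50 tie yields 'none' (logged)."""
    if c.total == 0:
        return NO_DOMINANCE
    if c.deoxy_share > 50.0:
        return DEO_DOMINANT
    if c.hydroxy_share > 50.0:
        return HYD_DOMINANT
    logger.warning("sample %r is exactly 50/50 deoxy/hydroxy; no dominance", c.sample_id)
    return NO_DOMINANCE


# --- composition PCA -------------------------------------------------------

#: composite loadings used for the ordination
COMPOSITE_VARIABLES = {
    "PEL": ("pelargonidin",),
    "CYA_PEO": ("cyanidin", "peonidin"),
    "DEL_MAL": ("delphinidin", "malvidin"),
    "DEO": ("apigenidin", "luteolinidin", "unknown_deoxy"),
}


def composite_table(compositions: list[PigmentComposition]) -> pd.DataFrame:
    """Samples x 4 matrix of composite anthocyanidin percentages."""
    rows = {
        c.sample_id: {
            name: sum(c.get(m) for m in members)
            for name, members in COMPOSITE_VARIABLES.items()
        }
        for c in compositions
    }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class PCAResult:
    variance_fractions: np.ndarray  # ordered, sums to 1
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # variables x components


def composition_pca(
    table: pd.DataFrame,
    scale: bool = True,
    drop_zero_rows: bool = False,
) -> PCAResult:
    """PCA of the composite composition table.

    Centered, and by default unit-scaled (correlation PCA). With
    `drop_zero_rows`, anthocyanin-free samples are removed first.
    """
    if drop_zero_rows:
        table = table.loc[table.sum(axis=1) > 0]
    if len(table) < 5:
        raise ValueError(f"need at least 5 samples for a PCA, got {len(table)}")
    x = table.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = table.columns[sd == 0].tolist()
            raise ValueError(f"constant column(s) {bad} cannot be unit-scaled")
        x = x / sd
    if not np.any(x):
        raise ValueError("all samples identical: variance fractions undefined")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2
    comps = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        variance_fractions=var / var.sum(),
        scores=pd.DataFrame(u * s, index=table.index, columns=comps),
        loadings=pd.DataFrame(vt.T, index=table.columns, columns=comps),
    )


# --- combination tallies ---------------------------------------------------

#: named pairwise co-occurrences tallied across samples
NAMED_PAIRS = {
    "PEL_with_CYA_PEO": (("pelargonidin",), ("cyanidin", "peonidin")),
    "CYA_PEO_with_DEL_MAL": (("cyanidin", "peonidin"), ("delphinidin", "malvidin")),
    "PEL_with_DEL_MAL": (("pelargonidin",), ("delphinidin", "malvidin")),
}


@dataclass
class CombinationTally:
    n_samples: int
    n_no_anthocyanin: int
    size_counts: dict[int, int]  # distinct-anthocyanidin count -> samples
    pair_counts: dict[str, int]

    def size_fraction(self, size: int) -> float:
        """Share of all samples (anthocyanin-free included) with `size` types."""
        return self.size_counts.get(size, 0) / self.n_samples


def combination_frequencies(
    compositions: list[PigmentComposition],
    presence_threshold_pct: float = 0.0,
) -> CombinationTally:
    """Tally per-sample anthocyanidin sets and named pairwise combinations.

    A pigment counts as present when its relative percentage exceeds
    `presence_threshold_pct` (default: any positive amount). The
    anthocyanin-free samples stay in the denominator of size fractions.
    """
    size_counts: dict[int, int] = {}
    pair_counts = {name: 0 for name in NAMED_PAIRS}
    n_none = 0
    for c in compositions:
        present = {n for n, p in c.percentages.items() if p > presence_threshold_pct}
        if not present:
            n_none += 1
            continue
        size_counts[len(present)] = size_counts.get(len(present), 0) + 1
        for name, (side_a, side_b) in NAMED_PAIRS.items():
            if present & set(side_a) and present & set(side_b):
                pair_counts[name] += 1
    return CombinationTally(
        n_samples=len(compositions),
        n_no_anthocyanin=n_none,
        size_counts=size_counts,
        pair_counts=pair_counts,
    )


def read_compositions(path, sep: str | None = None) -> list[PigmentComposition]:
    """Read a delimited composition table: sample_id + one column per anthocyanidin."""
    frame = pd.read_csv(path, sep=sep, engine="python")
    if "sample_id" not in frame.columns:
        raise ValueError("composition table must have a sample_id column")
    pigment_cols = [c for c in frame.columns if c in ALL_ANTHOCYANIDINS]
    out = []
    for _, row in frame.iterrows():
        pcts = {c: float(row[c]) for c in pigment_cols if float(row[c]) != 0.0}
        out.append(PigmentComposition(sample_id=str(row["sample_id"]), percentages=pcts))
    return out


def write_compositions(compositions: list[PigmentComposition], path, sep: str = ",") -> None:
    rows = [
        {"sample_id": c.sample_id, **{n: c.get(n) for n in ALL_ANTHOCYANIDINS}}
        for c in compositions
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
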