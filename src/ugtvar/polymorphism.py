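"""Genotype-frequency and AUC-ratio summaries for UGT polymorphisms.

Presentation-layer arithmetic only: genotype counts (wild type / heterozygous
/ homozygous variant) become frequencies, and per-genotype AUC group means
become percentages of the wild-type group.  No statistical testing of the
genotype effect is performed — significance in the underlying studies is
reported by those studies, not recomputed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "GenotypeCounts",
    "AucByGenotype",
    "genotype_frequencies",
    "auc_ratio_to_wildtype",
    "read_genotype_counts",
    "read_auc_by_genotype",
]

WILD_TYPE = "wt/wt"
GENOTYPES = (WILD_TYPE, "wt/var", "var/var")


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype counts for one SNP in one population."""

    population: str
    snp_id: str
    counts: tuple[int, int, int]  # wt/wt, wt/var, var/var

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("genotype counts must be nonnegative")


@dataclass(frozen=True)
class AucByGenotype:
    """Group (geometric) mean AUCs keyed by genotype, one substrate."""

    substrate: str
    auc_values: dict[str, float]


def genotype_frequencies(gc: GenotypeCounts) -> tuple[float, float, float]:
    """Genotype frequencies (sum to 1); all-zero counts are an error."""
    total = sum(gc.counts)
    if total == 0:
        raise ValueError(f"{gc.snp_id} in {gc.population}: all genotype counts are zero")
    return tuple(c / total for c in gc.counts)


def auc_ratio_to_wildtype(abg: AucByGenotype) -> dict[str, float]:
    """Each genotype's AUC as a percentage of the wild-type group (wt/wt = 100)."""
    if WILD_TYPE not in abg.auc_values:
        raise ValueError(f"{abg.substrate}: no wild-type (wt/wt) AUC value")
    wt = abg.auc_values[WILD_TYPE]
    if wt <= 0:
        raise ValueError(f"{abg.substrate}: wild-type AUC must be positive")
    return {g: 100.0 * v / wt for g, v in abg.auc_values.items()}


def read_genotype_counts(path: str | Path) -> list[GenotypeCounts]:
    """CSV columns: population, snp_id, wt_wt, wt_var, var_var."""
    frame = pd.read_csv(path)
    return [
        GenotypeCounts(
            population=str(r.population),
            snp_id=str(r.snp_id),
            counts=(int(r.wt_wt), int(r.wt_var), int(r.var_var)),
        )
        for r in frame.itertuples(index=False)
    ]


def read_auc_by_genotype(path: str | Path) -> list[AucByGenotype]:
    """CSV columns: substrate, genotype, auc (long format, grouped by substrate)."""
    frame = pd.read_csv(path)
    out = []
    for substrate, grp in frame.groupby("substrate", sort=False):
        out.append(
            AucByGenotype(
                substrate=str(substrate),
                auc_values={str(g): float(a) for g, a in zip(grp.genotype, grp.auc)},
            )
        )
    return out
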