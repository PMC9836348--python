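"""Score-distribution statistics, SD-cutoff hit calling and phenotype cross-tabs.

Suppressor hits are genes scoring strictly below ``mean - k*SD`` of the
score distribution (the deletion reduces the query's drug-resistant growth
relative to the multiplicative expectation); enhancer hits score strictly
above ``mean + k*SD``. Thresholds are always computed from unrounded
mean/SD; genes exactly at a threshold are non-hits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ValidationError


class InsufficientDataError(ValueError):
    """Fewer than two valid scores: no distribution to summarize."""


@dataclass(frozen=True)
class ScoreDistribution:
    """Summary statistics of an interaction-score distribution."""

    n: int
    mean: float
    sd: float
    min: float
    max: float

    def cutoffs(self, k_sd: float) -> tuple[float, float]:
        """(lower, upper) thresholds at ``mean -/+ k_sd * sd``."""
        return self.mean - k_sd * self.sd, self.mean + k_sd * self.sd


@dataclass
class HitSet:
    """Suppressor/enhancer calls at one SD-cutoff multiplier."""

    k_sd: float
    lower: float
    upper: float
    suppressors: list[str]
    enhancers: list[str]

    @property
    def genes(self) -> set[str]:
        return set(self.suppressors) | set(self.enhancers)


@dataclass
class PhenotypeCrosstab:
    """Hits split by prior drug-phenotype annotation.

    Genes annotated with *both* resistance and sensitivity (conflicting
    reports) are excluded from the four cells and counted separately;
    unannotated hits land in ``unannotated``.
    """

    sensitive_suppressors: list[str]
    resistant_suppressors: list[str]
    sensitive_enhancers: list[str]
    resistant_enhancers: list[str]
    both_annotated: list[str]
    unannotated: list[str]

    def counts(self) -> dict[str, int]:
        return {
            "sensitive_suppressors": len(self.sensitive_suppressors),
            "resistant_suppressors": len(self.resistant_suppressors),
            "sensitive_enhancers": len(self.sensitive_enhancers),
            "resistant_enhancers": len(self.resistant_enhancers),
            "both_annotated": len(self.both_annotated),
            "unannotated": len(self.unannotated),
        }


def _scores_series(scores) -> pd.Series:
    if isinstance(scores, pd.DataFrame):
        if not {"gene", "score"} <= set(scores.columns):
            raise ValidationError("score table needs 'gene' and 'score' columns")
        s = scores.set_index("gene")["score"].astype(float)
    else:
        s = pd.Series(np.asarray(scores, dtype=float))
        s.index = [f"g{i}" for i in range(len(s))]
    return s.dropna()


def score_stats(scores, ddof: int = 1) -> ScoreDistribution:
    """Summarize a score distribution (sample SD by default, ``ddof=0`` for
    population SD)."""
    s = _scores_series(scores)
    if len(s) < 2:
        raise InsufficientDataError(f"need >= 2 scores, got {len(s)}")
    arr = s.to_numpy()
    return ScoreDistribution(
        n=len(arr),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=ddof)),
        min=float(arr.min()),
        max=float(arr.max()),
    )


def classify_hits(scores, k_sd: float, dist: ScoreDistribution | None = None,
                  ddof: int = 1) -> HitSet:
    """Call suppressor/enhancer hits at ``mean -/+ k_sd * SD``.

    Strict inequalities against the unrounded thresholds; ties at a
    threshold are conservative non-hits.
    """
    s = _scores_series(scores)
    if dist is None:
        dist = score_stats(pd.DataFrame({"gene": s.index, "score": s.to_numpy()}), ddof=ddof)
    lower, upper = dist.cutoffs(k_sd)
    suppressors = sorted(s.index[s.to_numpy() < lower])
    enhancers = sorted(s.index[s.to_numpy() > upper])
    return HitSet(k_sd=k_sd, lower=lower, upper=upper,
                  suppressors=suppressors, enhancers=enhancers)


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "phenotype"} <= set(df.columns):
        raise ValidationError("annotation table needs 'gene' and 'phenotype' columns")
    return df


def crosstab_phenotypes(hits: HitSet, annotations: pd.DataFrame) -> PhenotypeCrosstab:
    """Cross-tabulate hits against prior resistant/sensitive annotations.

    ``annotations`` has columns (gene, phenotype) with phenotype in
    {resistant, sensitive, both, none}; genes may cover any subset of the
    hits. Duplicate gene rows are rejected.
    """
    allowed = {"resistant", "sensitive", "both", "none"}
    bad = set(annotations["phenotype"]) - allowed
    if bad:
        raise ValidationError(f"unknown phenotype values: {sorted(bad)}")
    if annotations["gene"].duplicated().any():
        dups = annotations.loc[annotations["gene"].duplicated(), "gene"].tolist()
        raise ValidationError(f"duplicate annotation rows for genes: {dups[:5]}")
    pheno = dict(zip(annotations["gene"], annotations["phenotype"]))

    cells = {"sensitive_suppressors": [], "resistant_suppressors": [],
             "sensitive_enhancers": [], "resistant_enhancers": []}
    both, unannotated = [], []
    for side, genes in (("suppressors", hits.suppressors), ("enhancers", hits.enhancers)):
        for g in genes:
            p = pheno.get(g, "none")
            if p == "both":
                both.append(g)
            elif p == "none":
                unannotated.append(g)
            else:
                cells[f"{p}_{side}"].append(g)
    return PhenotypeCrosstab(
        sensitive_suppressors=cells["sensitive_suppressors"],
        resistant_suppressors=cells["resistant_suppressors"],
        sensitive_enhancers=cells["sensitive_enhancers"],
        resistant_enhancers=cells["resistant_enhancers"],
        both_annotated=both,
        unannotated=unannotated,
    )
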