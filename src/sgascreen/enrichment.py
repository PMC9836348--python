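"""Term over-representation with the log10 observed/expected strength statistic.

For a query gene set of size n drawn from a background of N genes, a term
annotating K background genes and k query genes is tested with the
one-sided hypergeometric upper tail P(X >= k) (equivalent to one-sided
Fisher's exact on the 2x2 table). Effect size is reported as

    strength = log10( k / (n * K / N) )

the log10 ratio of observed to expected annotated genes in a random gene
set of the same size. P-values are adjusted per gene set with
Benjamini-Hochberg, and results are filtered/ranked the way screen tables
are reported: FDR cap, minimum gene count, strength-descending order, an
optional Jaccard redundancy filter, and a display cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .simulate import ValidationError

ENRICHMENT_COLUMNS = ["term", "name", "k", "n", "K", "N", "expected", "strength", "p", "fdr"]


@dataclass
class AnnotationSet:
    """Gene -> term annotations over a background universe.

    ``background`` defaults to the annotation universe (every gene with at
    least one annotation). Terms with no annotated genes are dropped.
    """

    term_genes: dict[str, set[str]]
    background: set[str]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.term_genes = {t: set(g) for t, g in self.term_genes.items() if g}
        stray = set().union(*self.term_genes.values(), set()) - self.background
        if stray:
            raise ValidationError(
                f"{len(stray)} annotated genes missing from background, e.g. {sorted(stray)[:3]}"
            )

    @classmethod
    def from_pairs(cls, pairs, background=None, names=None) -> "AnnotationSet":
        term_genes: dict[str, set[str]] = {}
        genes = set()
        for gene, term in pairs:
            term_genes.setdefault(str(term), set()).add(str(gene))
            genes.add(str(gene))
        bg = set(background) if background is not None else genes
        return cls(term_genes=term_genes, background=bg, names=dict(names or {}))

    @classmethod
    def from_tsv(cls, path, background=None, names=None) -> "AnnotationSet":
        """Two-column (gene, term) TSV, with or without a header line."""
        df = pd.read_csv(path, sep="\t", header=None, comment="!", dtype=str)
        if df.shape[1] < 2:
            raise ValidationError("annotation TSV needs >= 2 columns (gene, term)")
        first = df.iloc[0]
        if str(first[0]).lower() in ("gene", "orf", "systematic_name"):
            df = df.iloc[1:]
        return cls.from_pairs(df.iloc[:, :2].itertuples(index=False, name=None),
                              background=background, names=names)

    @classmethod
    def from_gaf(cls, path, background=None) -> "AnnotationSet":
        """GAF 2.x annotation file: DB Object ID (col 2) -> GO ID (col 5)."""
        pairs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("!"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 5:
                    continue
                pairs.append((parts[1], parts[4]))
        if not pairs:
            raise ValidationError("no annotation rows parsed from GAF file")
        return cls.from_pairs(pairs, background=background)


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """One-sided over-representation p-value P(X >= k), X ~ Hypergeom(N, K, n).

    Identical to a one-sided Fisher's exact test on the corresponding 2x2
    table.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValidationError(f"impossible table: k={k}, n={n}, K={K}, N={N}")
    if n - k > N - K:
        raise ValidationError(f"impossible table: only {N - K} unannotated genes, need {n - k}")
    return float(hypergeom.sf(k - 1, N, K, n))


def strength(k: int, n: int, K: int, N: int) -> float:
    """log10 of observed over expected annotated genes: log10(k / (n*K/N))."""
    if k < 1 or K < 1 or n < 1 or N < 1:
        raise ValidationError("strength requires k, n, K, N >= 1")
    return math.log10(k / (n * K / N))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, tie-safe)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_gene_set(
    genes,
    annotations: AnnotationSet,
    background_mode: str = "annotation_universe",
    custom_background: set[str] | None = None,
) -> pd.DataFrame:
    """Over-representation of every term in one query gene set.

    The background is the annotation universe by default, or a caller
    supplied universe (e.g. all screened genes) with
    ``background_mode="custom"``. Query genes outside the background are
    dropped (their count is reported in ``result.attrs["n_dropped"]``).
    Only terms with k >= 1 annotated query genes appear; FDR is adjusted
    across all terms tested for this gene set.
    """
    if background_mode == "annotation_universe":
        bg = annotations.background
    elif background_mode == "custom":
        if not custom_background:
            raise ValidationError("custom background_mode requires custom_background")
        bg = set(custom_background)
    else:
        raise ValidationError(f"unknown background_mode {background_mode!r}")

    query = {str(g) for g in genes}
    dropped = len(query - bg)
    query &= bg
    result = pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    if not query:
        result.attrs["n_dropped"] = dropped
        return result
    n, N = len(query), len(bg)
    rows = []
    for term, tg in annotations.term_genes.items():
        tg_bg = tg & bg
        K = len(tg_bg)
        k = len(tg_bg & query)
        if k < 1 or K < 1:
            continue
        expected = n * K / N
        rows.append((term, annotations.names.get(term, term), k, n, K, N,
                     expected, strength(k, n, K, N), hypergeom_test(k, n, K, N)))
    if rows:
        result = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
        result["fdr"] = bh_fdr(result["p"].to_numpy())
        result = result.sort_values(["p", "term"]).reset_index(drop=True)
    result.attrs["n_dropped"] = dropped
    return result


def curate_rank(
    rows: pd.DataFrame,
    annotations: AnnotationSet | None = None,
    fdr_max: float = 0.05,
    min_genes: int = 1,
    top_n: int | None = 10,
    redundancy_jaccard: float | None = None,
    term_blocklist: set[str] | None = None,
) -> pd.DataFrame:
    """Filter and rank one gene set's enrichment rows for reporting.

    Keeps rows with fdr <= fdr_max and k >= min_genes, drops blocklisted
    terms, sorts by strength descending (ties: smaller fdr, then term id),
    optionally drops terms whose annotated gene set overlaps a
    better-ranked kept term at Jaccard >= ``redundancy_jaccard`` (an
    automated stand-in for manual redundancy curation), and truncates to
    ``top_n`` rows.
    """
    if rows.empty:
        return rows.copy()
    kept = rows[(rows["fdr"] <= fdr_max) & (rows["k"] >= min_genes)].copy()
    if term_blocklist:
        kept = kept[~kept["term"].isin(term_blocklist)]
    kept = kept.sort_values(["strength", "fdr", "term"],
                            ascending=[False, True, True]).reset_index(drop=True)
    if redundancy_jaccard is not None:
        if annotations is None:
            raise ValidationError("redundancy filtering needs the AnnotationSet")
        selected: list[int] = []
        kept_sets: list[set[str]] = []
        for i, term in enumerate(kept["term"]):
            tg = annotations.term_genes.get(term, set())
            redundant = any(
                len(tg & prev) / len(tg | prev) >= redundancy_jaccard
                for prev in kept_sets if tg | prev
            )
            if not redundant:
                selected.append(i)
                kept_sets.append(tg)
        kept = kept.iloc[selected].reset_index(drop=True)
    if top_n is not None:
        kept = kept.head(top_n).reset_index(drop=True)
    return kept


def report_frame(rows: pd.DataFrame) -> pd.DataFrame:
    """Report-shaped view: term, no. of proteins, strength (2 d.p.), FDR."""
    out = rows[["name", "k", "strength", "fdr"]].copy()
    out.columns = ["GO term", "No. of proteins", "Strength", "False discovery rate"]
    out["Strength"] = out["Strength"].round(2)
    return out
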