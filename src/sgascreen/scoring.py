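"""Plate normalization and the 0-2 multiplicative interaction score.

The screen measures, for every array gene, colony sizes of the library
single knockout and of the query x knockout double mutant in rich medium
(YPD) and under drug, alongside wild-type and query-parent controls. Each
strain's *condition response* is its drug/YPD growth ratio normalized by
the wild type's ratio on the same plates:

    w = (size_drug / size_ypd) / (wt_drug / wt_ypd)

Under the multiplicative null the double mutant's response is the product
of its parents' responses, so the interaction ratio

    rho_hat = w_double / (w_query * w_single)

equals 1 for no interaction. The reported score is rho_hat clamped to
[0, s_max] (default ceiling 2): 0 = no growth of the double mutant under
drug (strong negative interaction), 1 = exactly the multiplicative
expectation, 2 = far better growth than expected (strong positive
interaction).

Before scoring, each physical plate layer (plate x strain class x
condition) is normalized: the layer median is scaled to the table's grand
median, a multiplicative row-then-column median polish removes plate
gradients, and the outermost ring is rescaled by the edge/interior median
ratio. Control ratios are taken from control colonies on the same layers,
so per-layer scale factors cancel exactly in the score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import BLANK, COLS, QUERY, ROWS, WT, ValidationError  # noqa: F401


class UndefinedRatioError(ValueError):
    """A condition-response ratio has a zero or negative denominator."""


# ---------------------------------------------------------------------------
# plate normalization


def _grid(layer: pd.DataFrame) -> np.ndarray:
    g = np.full((ROWS, COLS), np.nan)
    r = layer["row"].to_numpy(int) - 1
    c = layer["col"].to_numpy(int) - 1
    vals = layer["size"].to_numpy(float).copy()
    vals[layer["missing"].to_numpy(bool)] = np.nan
    g[r, c] = vals
    return g


def _safe_median(values: np.ndarray) -> float:
    finite = values[np.isfinite(values)]
    return float(np.median(finite)) if finite.size else float("nan")


def _line_medians(est: np.ndarray, axis: int, min_count: int = 8) -> np.ndarray:
    """Per-row/column medians of the estimation grid (NaN below min_count)."""
    out = np.full(est.shape[1 - axis], np.nan)
    for i in range(out.size):
        line = est[i, :] if axis == 1 else est[:, i]
        finite = line[np.isfinite(line) & (line > 0)]
        if finite.size >= min_count:
            out[i] = np.median(finite)
    return out


def _polish_once(grid: np.ndarray, est: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One multiplicative row-then-column median-polish pass.

    Spatial factors are estimated from ``est`` (array-gene colonies only,
    so control strains with different fitness cannot masquerade as plate
    gradients) and applied to every position of ``grid``. Row/column
    medians are rescaled to geometric mean 1 before dividing, so the
    polish removes relative gradients without changing the layer's scale;
    lines with too few usable colonies keep a factor of 1.
    """
    for axis in (1, 0):  # rows first, then columns
        med = _line_medians(est, axis)
        ok = np.isfinite(med)
        if ok.sum() >= 2:
            gmean = math.exp(np.mean(np.log(med[ok])))
            factors = np.where(ok, med / gmean, 1.0)
        else:
            factors = np.ones_like(med)
        shape = (-1, 1) if axis == 1 else (1, -1)
        grid = grid / factors.reshape(shape)
        est = est / factors.reshape(shape)
    return grid, est


_EDGE_MASK = np.zeros((ROWS, COLS), dtype=bool)
_EDGE_MASK[0, :] = _EDGE_MASK[-1, :] = True
_EDGE_MASK[:, 0] = _EDGE_MASK[:, -1] = True


def normalize_plates(
    table: pd.DataFrame,
    min_nonmissing_frac: float = 0.5,
    polish_iterations: int = 1,
) -> pd.DataFrame:
    """Normalize every plate layer for scale, gradients and edge effects.

    Per (plate, condition, strain_class) layer: (1) scale so the layer
    median of non-missing sizes equals the table grand median; (2)
    multiplicative row/column median polish; (3) divide the outermost ring
    by the edge/interior median ratio. Missing positions stay missing.
    Layers with fewer than ``min_nonmissing_frac`` non-missing positions
    are flagged unusable: their records are marked missing so downstream
    genes become invalid. The returned table lists those layers in
    ``result.attrs["unusable_layers"]``.
    """
    table = table.copy()
    nonmissing = ~table["missing"].to_numpy(bool)
    if not nonmissing.any():
        raise ValidationError("colony table has no non-missing colonies")
    grand = float(np.median(table.loc[nonmissing, "size"]))
    unusable: list[tuple] = []
    new_size = table["size"].to_numpy(float).copy()
    new_missing = table["missing"].to_numpy(bool).copy()

    for key, layer in table.groupby(["plate", "condition", "strain_class"], sort=False):
        idx = layer.index.to_numpy()
        # BLANK positions are structurally empty, not lost measurements:
        # occupancy is judged over pinned positions only
        pinned = layer["gene"].to_numpy() != BLANK
        present = ~layer["missing"].to_numpy(bool) & pinned
        if not pinned.any() or present.sum() / pinned.sum() < min_nonmissing_frac:
            unusable.append(key)
            new_missing[idx] = True
            continue
        grid = _grid(layer)
        # spatial/scale factors are estimated from colonies of the layer's
        # own strain population: on WT/QUERY lawn layers every colony
        # qualifies; on array layers the control tokens are other strains
        # and are excluded from estimation (corrections still apply to them)
        plate_name, condition, strain_class = key
        if strain_class in (WT, QUERY):
            est_layer = layer
        else:
            est_layer = layer[~layer["gene"].isin((WT, QUERY))]
        est = _grid(est_layer)
        med = _safe_median(est)
        if not np.isfinite(med) or med <= 0:
            unusable.append(key)
            new_missing[idx] = True
            continue
        scale = grand / med
        grid = grid * scale
        est = est * scale
        for _ in range(polish_iterations):
            grid, est = _polish_once(grid, est)
        edge_med = _safe_median(np.where(_EDGE_MASK, est, np.nan))
        int_med = _safe_median(np.where(_EDGE_MASK, np.nan, est))
        if np.isfinite(edge_med) and np.isfinite(int_med) and edge_med > 0 and int_med > 0:
            grid[_EDGE_MASK] /= edge_med / int_med
        r = layer["row"].to_numpy(int) - 1
        c = layer["col"].to_numpy(int) - 1
        vals = grid[r, c]
        new_size[idx] = np.where(np.isfinite(vals), vals, 0.0)

    table["size"] = new_size
    table["missing"] = new_missing
    table.loc[table["missing"], "size"] = 0.0
    table.attrs["unusable_layers"] = unusable
    return table


# ---------------------------------------------------------------------------
# interaction score


def condition_response(
    size_drug: float, size_ypd: float, wt_drug: float, wt_ypd: float
) -> float:
    """Drug/YPD growth ratio of a strain, normalized by the wild type's.

    The wild type's own response is exactly 1; a drug-resistant strain
    scores > 1 and a hypersensitive one < 1. ``size_drug`` may be 0 (no
    growth -> response 0); zero or negative denominators raise
    :class:`UndefinedRatioError` so the record can be marked invalid.
    """
    if size_ypd <= 0 or wt_ypd <= 0 or wt_drug <= 0:
        raise UndefinedRatioError(
            f"undefined response: size_ypd={size_ypd}, wt_ypd={wt_ypd}, wt_drug={wt_drug}"
        )
    if size_drug < 0:
        raise UndefinedRatioError(f"negative drug size {size_drug}")
    return (size_drug / size_ypd) / (wt_drug / wt_ypd)


def interaction_score(
    w_double: float, w_query: float, w_single: float, s_max: float = 2.0
) -> tuple[float, float]:
    """Interaction ratio and clamped 0-s_max score for one double mutant.

    rho_hat = w_double / (w_query * w_single); S = clamp(rho_hat, 0, s_max).
    """
    if w_query <= 0 or w_single <= 0:
        raise UndefinedRatioError(
            f"parent responses must be > 0 (w_query={w_query}, w_single={w_single})"
        )
    if w_double < 0:
        raise UndefinedRatioError(f"negative double-mutant response {w_double}")
    rho_hat = w_double / (w_query * w_single)
    return rho_hat, min(max(rho_hat, 0.0), s_max)


@dataclass
class ScoreResult:
    """Interaction scores plus per-replicate detail and the invalid list."""

    scores: pd.DataFrame      # gene, rho_hat, score, n_replicates, valid
    invalid: pd.DataFrame     # gene, reason
    records: pd.DataFrame     # per-replicate FitnessRecord detail
    s_max: float = 2.0

    def write_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index=False)


def score_table(
    normalized: pd.DataFrame,
    s_max: float = 2.0,
    aggregate: str = "geomean_rho",
    controls: str = "pooled",
) -> ScoreResult:
    """Compute one interaction score per array gene from a normalized table.

    Control medians come from the WT / QUERY control-token colonies on the
    same layer types as the measured colonies: WT tokens on the SINGLE_KO
    layers reference w_single, WT and QUERY tokens on the DKO layers
    reference w_double and w_query. With ``controls="pooled"`` (default)
    control colonies are pooled across replicate plates — a strain's drug
    response is a strain property, and pooling suppresses the plate-wide
    bias a handful of control colonies would otherwise impose;
    ``controls="per_plate"`` keeps plate-local references.

    Replicate positions are combined by the geometric mean of rho_hat
    before clamping (``aggregate="geomean_rho"``, unbiased under
    multiplicative noise) or the arithmetic mean of per-replicate scores
    (``aggregate="mean_score"``). Genes with no valid replicate are listed
    in ``invalid`` with a reason code.
    """
    if aggregate not in ("mean_score", "geomean_rho"):
        raise ValidationError(f"unknown aggregate {aggregate!r}")
    if controls not in ("pooled", "per_plate"):
        raise ValidationError(f"unknown controls mode {controls!r}")
    required = {("SINGLE_KO", "YPD"), ("SINGLE_KO", "DRUG"), ("DKO", "YPD"), ("DKO", "DRUG")}
    have = set(map(tuple, normalized[["strain_class", "condition"]].drop_duplicates().to_numpy()))
    if not required <= have:
        raise ValidationError(f"normalized table lacks layers: {sorted(required - have)}")

    # per-layer control medians (WT / QUERY token colonies on the array layers)
    ctrl = normalized[
        normalized["gene"].isin((WT, QUERY))
        & normalized["strain_class"].isin(("SINGLE_KO", "DKO"))
        & ~normalized["missing"]
        & (normalized["size"] > 0)
    ]
    ctrl_names = {
        ("SINGLE_KO", "YPD", WT): "wt_s_y",
        ("SINGLE_KO", "DRUG", WT): "wt_s_d",
        ("DKO", "YPD", WT): "wt_d_y",
        ("DKO", "DRUG", WT): "wt_d_d",
        ("DKO", "YPD", QUERY): "q_y",
        ("DKO", "DRUG", QUERY): "q_d",
    }
    control_frame = None
    if controls == "per_plate":
        ctrl_med = ctrl.groupby(["plate", "strain_class", "condition", "gene"])["size"].median()
        for key, name in ctrl_names.items():
            try:
                sub = ctrl_med.xs(key, level=(1, 2, 3)).rename(name).reset_index()
            except KeyError:
                sub = pd.DataFrame({"plate": [], name: []})
            control_frame = sub if control_frame is None else control_frame.merge(
                sub, on="plate", how="outer")
    else:
        # pool across replica plates of the same layout (identical gene
        # composition, hence identical layer-scaling bias); layouts are
        # identified by their gene position map, not by plate-id parsing
        ref = normalized[
            (normalized["strain_class"] == "SINGLE_KO")
            & (normalized["condition"] == "YPD")
        ]
        group_of = {
            plate: frozenset(zip(sub["row"], sub["col"], sub["gene"]))
            for plate, sub in ref.groupby("plate")[["row", "col", "gene"]]
        }
        group_ids: dict[frozenset, int] = {}
        plate_group = {
            plate: group_ids.setdefault(sig, len(group_ids))
            for plate, sig in group_of.items()
        }
        ctrl = ctrl.assign(group=ctrl["plate"].map(plate_group))
        ctrl_med = ctrl.groupby(["group", "strain_class", "condition", "gene"])["size"].median()
        for key, name in ctrl_names.items():
            try:
                sub = ctrl_med.xs(key, level=(1, 2, 3)).rename(name).reset_index()
            except KeyError:
                sub = pd.DataFrame({"group": [], name: []})
            control_frame = sub if control_frame is None else control_frame.merge(
                sub, on="group", how="outer")

    arr = normalized[
        ~normalized["gene"].isin((WT, QUERY, BLANK))
        & normalized["strain_class"].isin(("SINGLE_KO", "DKO"))
    ]
    idx = ["plate", "row", "col", "gene"]
    size_w = arr.pivot_table(index=idx, columns=["strain_class", "condition"],
                             values="size", aggfunc="first")
    miss_w = arr.pivot_table(index=idx, columns=["strain_class", "condition"],
                             values="missing", aggfunc="first")
    records = size_w.index.to_frame(index=False)

    def col(w, cls, cond, default):
        if (cls, cond) in w.columns:
            return w[(cls, cond)].to_numpy(float)
        return np.full(len(w), default)

    s_sy = col(size_w, "SINGLE_KO", "YPD", 0.0)
    s_sd = col(size_w, "SINGLE_KO", "DRUG", 0.0)
    s_dy = col(size_w, "DKO", "YPD", 0.0)
    s_dd = col(size_w, "DKO", "DRUG", 0.0)
    m_sy = col(miss_w, "SINGLE_KO", "YPD", 1.0) > 0
    m_sd = col(miss_w, "SINGLE_KO", "DRUG", 1.0) > 0
    m_dy = col(miss_w, "DKO", "YPD", 1.0) > 0
    m_dd = col(miss_w, "DKO", "DRUG", 1.0) > 0

    ctrl_cols = ["wt_s_y", "wt_s_d", "wt_d_y", "wt_d_d", "q_y", "q_d"]
    if control_frame is not None and controls == "per_plate":
        records = records.merge(control_frame, on="plate", how="left")
    elif control_frame is not None:
        records["group"] = records["plate"].map(plate_group)
        records = records.merge(control_frame, on="group", how="left").drop(columns="group")
    for c in ctrl_cols:
        if c not in records.columns:
            records[c] = np.nan
    ctrl_arr = records[ctrl_cols].to_numpy(float)
    ctrl_ok = np.isfinite(ctrl_arr).all(axis=1) & (ctrl_arr > 0).all(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        wt_s = records["wt_s_d"].to_numpy() / records["wt_s_y"].to_numpy()
        wt_d = records["wt_d_d"].to_numpy() / records["wt_d_y"].to_numpy()
        w_single = (s_sd / s_sy) / wt_s
        w_query = (records["q_d"].to_numpy() / records["q_y"].to_numpy()) / wt_d
        w_double = (s_dd / s_dy) / wt_d
        rho_hat = w_double / (w_query * w_single)

    reason = np.select(
        [
            m_sy, m_sd, m_dy, m_dd,
            ~ctrl_ok,
            (s_sy <= 0) | (s_dy <= 0),
            w_single <= 0,
            w_query <= 0,
        ],
        [
            "missing_single_ypd", "missing_single_drug",
            "missing_double_ypd", "missing_double_drug",
            "bad_controls",
            "zero_ypd",
            "zero_single_response",
            "zero_query_response",
        ],
        default="",
    )
    valid_mask = reason == ""
    records["w_single"] = np.where(valid_mask, w_single, np.nan)
    records["w_query"] = np.where(valid_mask, w_query, np.nan)
    records["w_double"] = np.where(valid_mask, w_double, np.nan)
    records["rho_hat"] = np.where(valid_mask, rho_hat, np.nan)
    records["score"] = np.where(valid_mask, np.clip(rho_hat, 0.0, s_max), np.nan)
    records["valid"] = valid_mask
    records["reason"] = reason
    records = records.drop(columns=ctrl_cols)
    valid = records[records["valid"]]
    if len(valid):
        grouped = valid.groupby("gene", sort=True)
        if aggregate == "mean_score":
            score = grouped["score"].mean()
            rho = grouped["rho_hat"].mean()
        else:
            rho = grouped["rho_hat"].apply(lambda v: float(np.exp(np.mean(np.log(np.maximum(v, 1e-300))))))
            score = rho.clip(0.0, s_max)
        scores = pd.DataFrame(
            {
                "gene": score.index,
                "rho_hat": rho.to_numpy(),
                "score": score.to_numpy(),
                "n_replicates": grouped.size().to_numpy(),
                "valid": True,
            }
        ).reset_index(drop=True)
    else:
        scores = pd.DataFrame(columns=["gene", "rho_hat", "score", "n_replicates", "valid"])

    scored = set(scores["gene"])
    inv = records[~records["valid"] & ~records["gene"].isin(scored)]
    first_reason = inv.groupby("gene", sort=True)["reason"].first()
    invalid = pd.DataFrame(
        {"gene": first_reason.index, "reason": first_reason.to_numpy()}
    ).reset_index(drop=True)
    return ScoreResult(scores=scores, invalid=invalid, records=records, s_max=s_max)


def read_score_tsv(path) -> pd.DataFrame:
    """Read a (gene, score) table; extra columns are ignored."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "score"} <= set(df.columns):
        raise ValidationError("score table needs 'gene' and 'score' columns")
    return df
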