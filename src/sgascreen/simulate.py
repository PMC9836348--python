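"""Synthetic SGA screens with known ground truth.

A condition-dependent SGA screen measures colony sizes for four strain
classes (wild type, query single mutant, library single knockouts, double
knockouts) in two conditions (rich medium and drug). Under the
multiplicative null model the double mutant's drug response is the product
of the query's and the single knockout's responses; a planted interaction
ratio ``rho`` multiplies that expectation (rho < 1: negative interaction /
suppressor of the query's drug-resistant growth, rho > 1: positive /
enhancer, rho = 1: no interaction).

The generator produces 384-format plate layouts (16 rows x 24 columns),
per-position colony sizes (pixel counts) for every strain class x condition
layer, optional spatial artifacts (row/column gradients, an edge-ring
multiplier), lognormal multiplicative noise, random missing colonies, and
rendered grayscale plate images. Everything is seeded and deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROWS = 16
COLS = 24
POSITIONS = ROWS * COLS

WT = "WT"
QUERY = "QUERY"
BLANK = "BLANK"
CONTROL_TOKENS = frozenset({WT, QUERY, BLANK})

STRAIN_CLASSES = (WT, QUERY, "SINGLE_KO", "DKO")
CONDITIONS = ("YPD", "DRUG")

COLONY_COLUMNS = [
    "plate", "row", "col", "gene", "strain_class", "condition", "size", "missing",
]


class ValidationError(ValueError):
    """Raised on invalid generator parameters or inconsistent inputs."""


@dataclass
class ScreenTruth:
    """Planted per-gene parameters of a synthetic screen.

    Attributes
    ----------
    genes : list of str
        Array gene identifiers.
    f_ypd : dict
        Baseline relative fitness of each single knockout on rich medium
        (unitless, > 0; 1 = grows like wild type).
    m_drug : dict
        Condition multiplier of each single knockout under drug, relative
        to wild type's own drug response (unitless, > 0).
    m_drug_query : float
        Condition multiplier of the query mutant under drug.
    query_fitness_ypd : float
        Query fitness on rich medium (default 1: healthy on YPD).
    rho : dict
        Planted interaction ratio per gene (>= 0; 1 = no interaction).
    gene_class : dict
        One of ``{"suppressor", "enhancer", "neutral"}`` per gene.
    """

    genes: list[str]
    f_ypd: dict[str, float]
    m_drug: dict[str, float]
    m_drug_query: float
    rho: dict[str, float]
    gene_class: dict[str, str]
    query_fitness_ypd: float = 1.0

    def __post_init__(self) -> None:
        for g in self.genes:
            r, c = self.rho[g], self.gene_class[g]
            if not np.isfinite(r) or r < 0:
                raise ValidationError(f"rho[{g}] must be finite and >= 0, got {r}")
            if (r < 1) != (c == "suppressor") or (r > 1) != (c == "enhancer"):
                raise ValidationError(
                    f"class/rho mismatch for {g}: rho={r}, class={c}"
                )
            if self.f_ypd[g] < 0 or self.m_drug[g] < 0:
                raise ValidationError(f"negative fitness multiplier for {g}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "f_ypd": [self.f_ypd[g] for g in self.genes],
                "m_drug": [self.m_drug[g] for g in self.genes],
                "rho": [self.rho[g] for g in self.genes],
                "class": [self.gene_class[g] for g in self.genes],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, m_drug_query: float = 2.0, query_fitness_ypd: float = 1.0
    ) -> "ScreenTruth":
        genes = df["gene"].tolist()
        return cls(
            genes=genes,
            f_ypd=dict(zip(genes, df["f_ypd"].astype(float))),
            m_drug=dict(zip(genes, df["m_drug"].astype(float))),
            m_drug_query=m_drug_query,
            rho=dict(zip(genes, df["rho"].astype(float))),
            gene_class=dict(zip(genes, df["class"])),
            query_fitness_ypd=query_fitness_ypd,
        )


@dataclass
class PlateLayout:
    """Mapping of a 16x24 plate to genes and control tokens (1-based)."""

    plate_id: str
    gene_at: dict[tuple[int, int], str]  # (row, col) -> gene id or token

    def positions(self):
        for r in range(1, ROWS + 1):
            for c in range(1, COLS + 1):
                yield r, c, self.gene_at[(r, c)]

    @property
    def genes(self) -> list[str]:
        return [g for _, _, g in self.positions() if g not in CONTROL_TOKENS]


@dataclass
class ArtifactParams:
    """Spatial artifact and noise parameters for a simulated screen.

    ``row_gradient`` / ``col_gradient`` are maximum fractional amplitudes of
    a linear multiplicative gradient across the plate; each physical layer
    draws its own signed amplitude uniformly in [-a, +a] (plates dry and
    get pinned independently). ``edge_effect`` multiplies the outermost
    ring of positions on every layer. ``noise_cv`` is the coefficient of
    variation of mean-preserving lognormal multiplicative noise.
    """

    row_gradient: float = 0.0
    col_gradient: float = 0.0
    edge_effect: float = 1.0
    noise_cv: float = 0.0
    missing_prob: float = 0.0
    base_size: float = 300.0

    def __post_init__(self) -> None:
        if self.row_gradient < 0 or self.col_gradient < 0:
            raise ValidationError("gradient amplitudes must be >= 0")
        if not (0 <= self.missing_prob < 1):
            raise ValidationError("missing_prob must be in [0, 1)")
        if self.base_size <= 0:
            raise ValidationError("base_size must be > 0")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.edge_effect < 0:
            raise ValidationError("edge_effect must be >= 0")

    @classmethod
    def clean(cls, base_size: float = 300.0) -> "ArtifactParams":
        """Artifact-free, noiseless parameters (exact multiplicative sizes)."""
        return cls(base_size=base_size)

    @classmethod
    def realistic(cls, base_size: float = 300.0) -> "ArtifactParams":
        """Plate artifacts typical of pinned colony arrays."""
        return cls(
            row_gradient=0.15,
            col_gradient=0.15,
            edge_effect=0.8,
            noise_cv=0.1,
            missing_prob=0.01,
            base_size=base_size,
        )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def generate_truth(
    n_genes: int,
    frac_suppressor: float = 0.1,
    frac_enhancer: float = 0.1,
    effect_low: float = 0.0,
    effect_high: float = 2.5,
    seed: int = 0,
    suppressor_high: float = 1.0,
    enhancer_low: float = 1.0,
    m_drug_query: float = 2.0,
    f_ypd_cv: float = 0.0,
    m_drug_cv: float = 0.0,
) -> ScreenTruth:
    """Draw planted ground truth for a synthetic screen.

    Exactly ``round(n_genes * frac)`` genes per hit class (half-up
    rounding). Suppressor rho ~ U[effect_low, suppressor_high), enhancer
    rho ~ U(enhancer_low, effect_high]; neutral genes have rho exactly 1.
    Baseline fitness ``f_ypd`` and drug multiplier ``m_drug`` default to 1
    for every gene (the planted signal lives in rho); optional lognormal
    spreads ``f_ypd_cv`` / ``m_drug_cv`` add per-gene fitness variation.
    """
    if n_genes < 0:
        raise ValidationError("n_genes must be >= 0")
    for name, frac in (("frac_suppressor", frac_suppressor), ("frac_enhancer", frac_enhancer)):
        if not (0 <= frac <= 1):
            raise ValidationError(f"{name} must be in [0, 1], got {frac}")
    if frac_suppressor + frac_enhancer > 1:
        raise ValidationError("hit fractions sum to more than 1")
    if not (0 <= effect_low < 1 < effect_high):
        raise ValidationError("need 0 <= effect_low < 1 < effect_high")
    if not (effect_low <= suppressor_high <= 1):
        raise ValidationError("suppressor_high must lie in [effect_low, 1]")
    if not (1 <= enhancer_low <= effect_high):
        raise ValidationError("enhancer_low must lie in [1, effect_high]")

    rng = np.random.default_rng(seed)
    width = max(4, len(str(max(n_genes, 1))))
    genes = [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]

    n_supp = _round_half_up(n_genes * frac_suppressor)
    n_enh = _round_half_up(n_genes * frac_enhancer)
    classes = np.array(
        ["suppressor"] * n_supp + ["enhancer"] * n_enh + ["neutral"] * (n_genes - n_supp - n_enh)
    )
    rng.shuffle(classes)

    rho = np.ones(n_genes)
    supp_mask = classes == "suppressor"
    enh_mask = classes == "enhancer"
    # half-open on the neutral side so rho never collides with 1
    rho[supp_mask] = rng.uniform(effect_low, suppressor_high, supp_mask.sum())
    rho[supp_mask] = np.minimum(rho[supp_mask], np.nextafter(1.0, 0.0))
    rho[enh_mask] = rng.uniform(enhancer_low, effect_high, enh_mask.sum())
    rho[enh_mask] = np.maximum(rho[enh_mask], np.nextafter(1.0, 2.0))

    def _lognormal(cv: float) -> np.ndarray:
        if cv <= 0:
            return np.ones(n_genes)
        sigma = math.sqrt(math.log1p(cv * cv))
        return rng.lognormal(-0.5 * sigma * sigma, sigma, n_genes)

    f_ypd = _lognormal(f_ypd_cv)
    m_drug = _lognormal(m_drug_cv)

    return ScreenTruth(
        genes=genes,
        f_ypd=dict(zip(genes, f_ypd)),
        m_drug=dict(zip(genes, m_drug)),
        m_drug_query=m_drug_query,
        rho=dict(zip(genes, rho)),
        gene_class=dict(zip(genes, classes)),
    )


def _control_positions(controls_per_plate: int) -> list[tuple[int, int, str]]:
    """Deterministic interior control positions, scattered over the plate.

    Controls avoid the outermost ring (edge artifacts must not be
    conflated with control growth) and are spread over distinct rows and
    columns so that no single row/column correction dominates a control
    strain's reference. Tokens alternate WT / QUERY, so every plate has at
    least one of each and both strains sample several rows.
    """
    scattered: list[tuple[int, int]] = [
        (2, 2), (15, 23), (5, 8), (12, 17), (8, 5), (9, 20), (3, 12), (14, 13),
        (2, 23), (15, 2), (12, 8), (5, 17), (6, 3), (11, 22), (4, 20), (13, 6),
        (7, 15), (10, 10), (3, 18), (14, 7), (6, 21), (11, 4), (8, 12), (9, 14),
    ]
    # additional interior positions if ever more controls are requested
    for r in range(2, ROWS):
        for c in range(2, COLS):
            if (r, c) not in scattered:
                scattered.append((r, c))
    if controls_per_plate > len(scattered):
        raise ValidationError("too many controls for interior placement")
    chosen = scattered[:controls_per_plate]
    return [(r, c, WT if i % 2 == 0 else QUERY) for i, (r, c) in enumerate(chosen)]


def layout_plates(
    truth: ScreenTruth, controls_per_plate: int = 4, seed: int = 0
) -> list[PlateLayout]:
    """Assign every gene to one position across as few 384-format plates as needed.

    Gene order is a seeded shuffle; control positions are fixed and
    identical on every plate. Unused positions on the last plate are BLANK.
    """
    if controls_per_plate < 2:
        raise ValidationError("need >= 2 controls per plate (one WT, one QUERY)")
    controls = _control_positions(controls_per_plate)
    per_plate = POSITIONS - controls_per_plate
    genes = list(truth.genes)
    if not genes:
        return []
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes))
    genes = [genes[i] for i in order]
    n_plates = math.ceil(len(genes) / per_plate)

    layouts = []
    it = iter(genes)
    control_at = {(r, c): tok for r, c, tok in controls}
    for p in range(1, n_plates + 1):
        gene_at: dict[tuple[int, int], str] = {}
        for r in range(1, ROWS + 1):
            for c in range(1, COLS + 1):
                if (r, c) in control_at:
                    gene_at[(r, c)] = control_at[(r, c)]
                else:
                    gene_at[(r, c)] = next(it, BLANK)
        layouts.append(PlateLayout(plate_id=f"p{p:02d}", gene_at=gene_at))
    return layouts


def replicate_layouts(layouts: list[PlateLayout], n_replicates: int) -> list[PlateLayout]:
    """Replica-pin each layout to ``n_replicates`` plate copies.

    Copies share gene positions but get distinct plate ids (``p01r01`` ...),
    so each carries independent artifacts and noise; scoring averages a
    gene's replicate positions across plates.
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    if n_replicates == 1:
        return list(layouts)
    return [
        PlateLayout(plate_id=f"{lay.plate_id}r{rep:02d}", gene_at=dict(lay.gene_at))
        for lay in layouts
        for rep in range(1, n_replicates + 1)
    ]


def spatial_field(
    row_amp: float, col_amp: float, edge_effect: float
) -> np.ndarray:
    """16x24 multiplicative spatial field for one physical plate layer.

    Row factor runs linearly from ``1 - a`` (row 1) to ``1 + a`` (row 16);
    columns likewise; the outermost ring is additionally multiplied by
    ``edge_effect``. Signed amplitudes are allowed (gradient direction).
    """
    r = np.arange(ROWS, dtype=float)
    c = np.arange(COLS, dtype=float)
    row_f = 1.0 + row_amp * (2.0 * r / (ROWS - 1) - 1.0)
    col_f = 1.0 + col_amp * (2.0 * c / (COLS - 1) - 1.0)
    field = np.outer(row_f, col_f)
    edge = np.ones((ROWS, COLS))
    edge[0, :] = edge[-1, :] = edge_effect
    edge[:, 0] = edge[:, -1] = edge_effect
    return field * edge


def simulate_screen(
    truth: ScreenTruth,
    layouts: list[PlateLayout],
    artifacts: ArtifactParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate colony sizes for every layout position x strain class x condition.

    Expected size = base_size * S(r, c) * F where S is the layer's spatial
    field and F the multiplicative fitness factor of the strain at that
    position. With ``noise_cv > 0`` sizes are drawn from a mean-preserving
    lognormal and rounded to integer pixel counts; with ``noise_cv == 0``
    sizes are the exact expectations (floats), so the noiseless screen
    round-trips through scoring exactly.

    Returns a ColonyTable DataFrame with columns
    plate, row, col, gene, strain_class, condition, size, missing.
    """
    if artifacts is None:
        artifacts = ArtifactParams.clean()
    placed = {g for lay in layouts for g in lay.genes}
    unknown = placed - set(truth.genes)
    if unknown:
        raise ValidationError(f"layouts reference unknown genes: {sorted(unknown)[:5]}")
    missing_genes = set(truth.genes) - placed
    if missing_genes:
        raise ValidationError(
            f"layouts do not cover all genes ({len(missing_genes)} unplaced)"
        )

    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(artifacts.noise_cv**2)) if artifacts.noise_cv > 0 else 0.0
    q_ypd = truth.query_fitness_ypd
    mq = truth.m_drug_query
    row_grid, col_grid = np.meshgrid(
        np.arange(1, ROWS + 1), np.arange(1, COLS + 1), indexing="ij"
    )
    frames = []
    for lay in layouts:
        tokens = np.array(
            [[lay.gene_at[(r, c)] for c in range(1, COLS + 1)] for r in range(1, ROWS + 1)],
            dtype=object,
        )
        flat = tokens.ravel()
        is_wt = flat == WT
        is_q = flat == QUERY
        is_blank = flat == BLANK
        is_gene = ~(is_wt | is_q | is_blank)
        f = np.where(is_gene, [truth.f_ypd.get(t, np.nan) for t in flat], np.nan)
        m = np.where(is_gene, [truth.m_drug.get(t, np.nan) for t in flat], np.nan)
        rho = np.where(is_gene, [truth.rho.get(t, np.nan) for t in flat], np.nan)

        wt_f = {"YPD": 1.0, "DRUG": 1.0}
        q_f = {"YPD": q_ypd, "DRUG": q_ypd * mq}
        for strain_class in STRAIN_CLASSES:
            for condition in CONDITIONS:
                if strain_class == WT:
                    factor = np.full(POSITIONS, wt_f[condition])
                    empty = np.zeros(POSITIONS, dtype=bool)
                elif strain_class == QUERY:
                    factor = np.full(POSITIONS, q_f[condition])
                    empty = np.zeros(POSITIONS, dtype=bool)
                else:
                    drug = condition == "DRUG"
                    if strain_class == "SINGLE_KO":
                        gene_factor = f * (m if drug else 1.0)
                    else:  # DKO
                        gene_factor = (rho * mq * m * f * q_ypd) if drug else f * q_ypd
                    factor = np.where(is_gene, gene_factor, 0.0)
                    factor = np.where(is_wt, wt_f[condition], factor)
                    factor = np.where(is_q, q_f[condition], factor)
                    empty = is_blank
                if artifacts.row_gradient > 0 or artifacts.col_gradient > 0:
                    ra = rng.uniform(-artifacts.row_gradient, artifacts.row_gradient)
                    ca = rng.uniform(-artifacts.col_gradient, artifacts.col_gradient)
                else:
                    ra = ca = 0.0
                S = spatial_field(ra, ca, artifacts.edge_effect).ravel()
                expected = artifacts.base_size * S * factor
                if sigma > 0:
                    noise = rng.lognormal(-0.5 * sigma * sigma, sigma, POSITIONS)
                    size = np.round(expected * noise)
                else:
                    size = expected
                if artifacts.missing_prob > 0:
                    dropped = rng.random(POSITIONS) < artifacts.missing_prob
                else:
                    dropped = np.zeros(POSITIONS, dtype=bool)
                missing = empty | dropped
                size = np.where(missing, 0.0, size)
                frames.append(
                    pd.DataFrame(
                        {
                            "plate": lay.plate_id,
                            "row": row_grid.ravel(),
                            "col": col_grid.ravel(),
                            "gene": flat,
                            "strain_class": strain_class,
                            "condition": condition,
                            "size": size.astype(float),
                            "missing": missing,
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)[COLONY_COLUMNS]


def write_colony_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_colony_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing_cols = set(COLONY_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"colony table missing columns: {sorted(missing_cols)}")
    df["missing"] = df["missing"].astype(bool)
    return df[COLONY_COLUMNS]


def render_plate_image(
    table: pd.DataFrame,
    plate_id: str,
    condition: str,
    strain_class: str,
    cell_px: int | None = None,
    foreground: int = 220,
) -> np.ndarray:
    """Render one physical plate layer as an 8-bit grayscale image.

    Each non-missing position becomes a filled disk of exactly ``size``
    foreground pixels (the ``size`` pixels nearest the cell center), so
    pixel counting recovers the recorded colony sizes; background is 0.
    Colonies larger than their grid cell are clipped to the cell.
    """
    layer = table[
        (table["plate"] == plate_id)
        & (table["condition"] == condition)
        & (table["strain_class"] == strain_class)
    ]
    if layer.empty:
        raise KeyError(f"no records for plate={plate_id!r} {strain_class}/{condition}")
    sizes = layer["size"].to_numpy(float)
    if cell_px is None:
        max_r = math.sqrt(max(sizes.max(), 1.0) / math.pi)
        cell_px = max(16, int(2 * math.ceil(max_r) + 6))
    # pixel offsets within one cell, ordered by distance from the center
    yy, xx = np.mgrid[0:cell_px, 0:cell_px]
    center = cell_px / 2 - 0.5
    dist2 = (yy - center) ** 2 + (xx - center) ** 2
    order = np.argsort(dist2.ravel(), kind="stable")
    off_y, off_x = np.unravel_index(order, (cell_px, cell_px))

    img = np.zeros((ROWS * cell_px, COLS * cell_px), dtype=np.uint8)
    for row, col, size, missing in zip(
        layer["row"], layer["col"], layer["size"], layer["missing"]
    ):
        n_px = int(round(float(size)))
        if missing or n_px <= 0:
            continue
        n_px = min(n_px, cell_px * cell_px)
        y0 = (int(row) - 1) * cell_px
        x0 = (int(col) - 1) * cell_px
        img[y0 + off_y[:n_px], x0 + off_x[:n_px]] = foreground
    return img


def simulate_module_network(
    genes: list[str],
    n_modules: int = 5,
    p_in: float = 0.5,
    p_out: float = 0.01,
    confidence_in: tuple[float, float] = (0.6, 0.95),
    confidence_out: tuple[float, float] = (0.4, 0.6),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Planted-module weighted edge list for a gene set (stochastic block model).

    Emulates a functional-association network export: genes are split into
    ``n_modules`` equal modules; within-module pairs get an edge with
    probability ``p_in`` (high confidence), cross-module pairs with
    ``p_out`` (low confidence). Returns (edge DataFrame with columns
    node1, node2, combined_score on the 0-1000 scale, planted module map).
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    modules = {g: i % n_modules + 1 for i, g in enumerate(genes)}
    rows = []
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            same = modules[a] == modules[b]
            if rng.random() < (p_in if same else p_out):
                lo, hi = confidence_in if same else confidence_out
                score = int(round(rng.uniform(lo, hi) * 1000))
                rows.append((a, b, score))
    return pd.DataFrame(rows, columns=["node1", "node2", "combined_score"]), modules


def simulate_annotations(
    modules: dict[str, int],
    background: list[str],
    genes_per_extra_term: int = 12,
    n_extra_terms: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-column gene->term annotation table with planted module terms.

    Each planted module becomes a term ``MODULE_k`` annotating exactly its
    member genes; random decoy terms annotate uniform draws from the
    background, so over-representation of the module terms is real and the
    decoys behave as nulls.
    """
    rng = np.random.default_rng(seed)
    rows = [(g, f"MODULE_{m}") for g, m in modules.items()]
    bg = list(background)
    for t in range(1, n_extra_terms + 1):
        picks = rng.choice(len(bg), size=min(genes_per_extra_term, len(bg)), replace=False)
        rows.extend((bg[i], f"DECOY_{t:03d}") for i in picks)
    return pd.DataFrame(rows, columns=["gene", "term"])
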