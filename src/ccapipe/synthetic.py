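"""Synthetic inputs with known ground truth for every pipeline stage.

Four families are generated: TMA scoring tables (two cores per tumor per
marker/compartment with ordinal quantity/intensity codes), two-channel
fluorescence fields (DAPI + stain; nuclei as disks, cytoplasm as
concentric annuli), expression cohorts with a planted high-CIN cluster
and exponential survival, and qPCR plates with planted knockdown
fractions.  Defaults mirror the cohort structure the pipeline targets:
152-tumor TMA cohorts, a 104-tumor / 6-normal expression cohort with a
25% high-CIN subgroup, and four-condition siRNA plates (scrambled,
siYAP, siTAZ, siYAP+siTAZ).

Every generator takes its seed from its spec and is bit-reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ihc import ACHIEVABLE_PRODUCTS

__all__ = [
    "TMACohortSpec",
    "IFFieldSpec",
    "ExpressionCohortSpec",
    "KnockdownPlateSpec",
    "SyntheticField",
    "PlacementError",
    "CIN25_SIGNATURE",
    "generate_tma_cohort",
    "generate_if_field",
    "generate_expression_cohort",
    "generate_knockdown_plate",
    "generate_density_cohort",
    "default_knockdown_fractions",
]

# 25-gene chromosomal-instability signature used as the default planted
# gene set.  The first seven symbols are canonical CIN genes; the
# remainder are editable placeholders for the user's full list (see also
# data/cin25_default.txt).
CIN25_SIGNATURE: tuple[str, ...] = (
    "AURKA", "AURKB", "CCNB1", "CCNB2", "FOXM1", "TOP2A", "TTK",
) + tuple(f"CIN_GENE_{i:02d}" for i in range(8, 26))


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without nuclear overlap."""


def _check_prob(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


# --------------------------------------------------------------------------
# TMA scoring tables
# --------------------------------------------------------------------------

def _default_positivity() -> dict[tuple[str, str], float]:
    # Marginal positivity rates of an intrahepatic 152-tumor cohort.
    return {
        ("YAP", "nuclear"): 0.395,
        ("TAZ", "nuclear"): 0.316,
        ("YAP", "cytoplasmic"): 0.283,
        ("TAZ", "cytoplasmic"): 0.026,
    }


def _default_score_dist() -> dict[int, float]:
    # Skewed toward low scores; the per-patient score distribution is a
    # free parameter of the generator, not an estimate.
    return {1: 0.15, 2: 0.15, 3: 0.15, 4: 0.15, 6: 0.15, 8: 0.10, 9: 0.10, 12: 0.05}


@dataclass
class TMACohortSpec:
    n_tumors: int = 152
    grade_probs: Mapping[str, float] = field(
        default_factory=lambda: {"G1": 9 / 152, "G2": 98 / 152, "G3": 42 / 152, "G4": 3 / 152}
    )
    marker_compartment_positivity: Mapping[tuple[str, str], float] = field(
        default_factory=_default_positivity
    )
    score_given_positive: Mapping[int, float] = field(default_factory=_default_score_dist)
    core_concordance: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumors < 1:
            raise ValueError("n_tumors must be >= 1")
        for g, p in self.grade_probs.items():
            _check_prob(p, f"grade_probs[{g}]")
        if abs(sum(self.grade_probs.values()) - 1.0) > 1e-9:
            raise ValueError("grade_probs must sum to 1")
        for key, p in self.marker_compartment_positivity.items():
            _check_prob(p, f"positivity{key}")
        bad = set(self.score_given_positive) - (ACHIEVABLE_PRODUCTS - {0})
        if bad:
            raise ValueError(f"score_given_positive has unachievable products: {sorted(bad)}")
        if abs(sum(self.score_given_positive.values()) - 1.0) > 1e-9:
            raise ValueError("score_given_positive must sum to 1")
        _check_prob(self.core_concordance, "core_concordance")


# all (quantity, intensity) factorizations of each achievable positive product
_FACTORIZATIONS: dict[int, list[tuple[int, int]]] = {
    p: [
        (q, i)
        for q, i in itertools.product(range(5), range(4))
        if q * i == p
    ]
    for p in sorted(ACHIEVABLE_PRODUCTS - {0})
}


def generate_tma_cohort(spec: TMACohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-core observations plus ground-truth positivity.

    Returns ``(observations, truth)``: observations has one row per
    core (two per tumor per marker/compartment) with quantity and
    intensity codes; truth carries the planted per-tumor positivity
    flag for each (marker, compartment).
    """
    rng = np.random.default_rng(spec.seed)
    grades = list(spec.grade_probs)
    grade_p = np.array([spec.grade_probs[g] for g in grades])
    scores = np.array(sorted(spec.score_given_positive))
    score_p = np.array([spec.score_given_positive[s] for s in scores])

    obs_rows, truth_rows = [], []
    for t in range(spec.n_tumors):
        tumor_id = f"T{t + 1:04d}"
        grade = grades[rng.choice(len(grades), p=grade_p)]
        for (marker, compartment), p_pos in spec.marker_compartment_positivity.items():
            positive = bool(rng.random() < p_pos)
            truth_rows.append(
                {
                    "tumor_id": tumor_id,
                    "marker": marker,
                    "compartment": compartment,
                    "true_positive": positive,
                }
            )

            def draw_codes() -> tuple[int, int]:
                if not positive:
                    return 0, 0
                product = int(scores[rng.choice(len(scores), p=score_p)])
                options = _FACTORIZATIONS[product]
                return options[rng.integers(len(options))]

            q1, i1 = draw_codes()
            if rng.random() < spec.core_concordance:
                q2, i2 = q1, i1
            else:
                q2, i2 = draw_codes()
            for core_id, (q, i) in ((1, (q1, i1)), (2, (q2, i2))):
                obs_rows.append(
                    {
                        "tumor_id": tumor_id,
                        "core_id": core_id,
                        "marker": marker,
                        "compartment": compartment,
                        "quantity": q,
                        "intensity": i,
                        "grade": grade,
                    }
                )
    return pd.DataFrame(obs_rows), pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------
# Two-channel fluorescence fields
# --------------------------------------------------------------------------

@dataclass
class IFFieldSpec:
    width: int = 256
    height: int = 256
    n_cells: int = 12
    nucleus_radius: tuple[float, float] = (6.0, 9.0)
    cell_radius: tuple[float, float] = (12.0, 16.0)
    nuclear_intensity: float = 200.0
    cytoplasmic_intensity: float = 100.0
    dapi_intensity: float = 180.0
    background: float = 10.0
    noise_sd: float = 5.0
    seed: int = 0
    max_attempts_per_cell: int = 500

    def __post_init__(self) -> None:
        if self.cell_radius[0] <= self.nucleus_radius[1]:
            raise ValueError("cell_radius must exceed nucleus_radius")
        if not (self.nuclear_intensity >= 0 and self.cytoplasmic_intensity >= 0):
            raise ValueError("intensities must be non-negative")
        if not 0 <= self.background <= min(self.nuclear_intensity, self.cytoplasmic_intensity):
            raise ValueError("background must satisfy intensities >= background >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


@dataclass
class SyntheticField:
    """A simulated two-channel field with its ground truth.

    ``channels`` has shape (2, H, W): channel 0 DAPI, channel 1 stain.
    ``true_ratio`` is nuclear over cytoplasmic stain intensity.
    """

    field_id: str
    channels: np.ndarray
    nuclear_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    n_cells: int
    true_ratio: float


def generate_if_field(spec: IFFieldSpec, field_id: str = "field") -> SyntheticField:
    """Render a field of non-overlapping nuclei with cytoplasmic annuli.

    Nuclei are disks; each cell's cytoplasm is the concentric annulus
    between the nuclear and cell radii.  Cells are placed by rejection
    sampling; if a nucleus cannot be placed within the attempt budget a
    :class:`PlacementError` names the density limit.  Pixel noise is
    Gaussian, truncated at zero.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]

    centers: list[tuple[float, float, float, float]] = []  # (y, x, r_nuc, r_cell)
    for i in range(spec.n_cells):
        placed = False
        for _ in range(spec.max_attempts_per_cell):
            r_nuc = rng.uniform(*spec.nucleus_radius)
            r_cell = rng.uniform(*spec.cell_radius)
            margin = r_cell + 1
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            if all(
                (cy - oy) ** 2 + (cx - ox) ** 2 > (r_nuc + orn + 1) ** 2
                for oy, ox, orn, _ in centers
            ):
                centers.append((cy, cx, r_nuc, r_cell))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place nucleus {i + 1}/{spec.n_cells} without overlap "
                f"after {spec.max_attempts_per_cell} attempts: field too dense for "
                f"{spec.n_cells} cells of radius <= {spec.cell_radius[1]} on "
                f"{w}x{h} px"
            )

    nuclear = np.zeros((h, w), dtype=bool)
    cell = np.zeros((h, w), dtype=bool)
    for cy, cx, r_nuc, r_cell in centers:
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        nuclear |= d2 <= r_nuc**2
        cell |= d2 <= r_cell**2
    cytoplasm = cell & ~nuclear

    dapi = np.full((h, w), spec.background, dtype=float)
    dapi[nuclear] = spec.dapi_intensity
    stain = np.full((h, w), spec.background, dtype=float)
    stain[cytoplasm] = spec.cytoplasmic_intensity
    stain[nuclear] = spec.nuclear_intensity
    if spec.noise_sd > 0:
        dapi += rng.normal(0.0, spec.noise_sd, size=dapi.shape)
        stain += rng.normal(0.0, spec.noise_sd, size=stain.shape)
    channels = np.clip(np.stack([dapi, stain]), 0.0, None)

    true_ratio = (
        spec.nuclear_intensity / spec.cytoplasmic_intensity
        if spec.cytoplasmic_intensity > 0
        else np.nan
    )
    return SyntheticField(
        field_id=field_id,
        channels=channels,
        nuclear_mask=nuclear,
        cytoplasm_mask=cytoplasm,
        n_cells=len(centers),
        true_ratio=true_ratio,
    )


def generate_density_cohort(
    n_fields: int = 200,
    count_range: tuple[int, int] = (5, 60),
    ratio_intercept: float = 3.0,
    ratio_slope: float = -0.03,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Field-level measurements with a planted density effect.

    Emulates a series of fields imaged at varying confluence where the
    nuclear/cytoplasmic ratio declines linearly with cell count; used
    for density-split and regression power checks without rendering
    images.
    """
    if n_fields < 2:
        raise ValueError("need at least 2 fields")
    rng = np.random.default_rng(seed)
    counts = rng.integers(count_range[0], count_range[1] + 1, size=n_fields)
    ratios = ratio_intercept + ratio_slope * counts + rng.normal(0, noise_sd, n_fields)
    ratios = np.clip(ratios, 0.05, None)
    return pd.DataFrame(
        {
            "field_id": [f"F{i + 1:04d}" for i in range(n_fields)],
            "nucleus_count": counts,
            "nc_ratio": ratios,
        }
    )


# --------------------------------------------------------------------------
# Expression cohort with planted CIN cluster and survival
# --------------------------------------------------------------------------

def _default_genes() -> tuple[tuple[str, ...], tuple[str, ...]]:
    background = tuple(f"BG_GENE_{i:04d}" for i in range(1, 151))
    return CIN25_SIGNATURE + background, CIN25_SIGNATURE


@dataclass
class ExpressionCohortSpec:
    n_tumors: int = 104
    n_normals: int = 6
    genes: Sequence[str] = field(default_factory=lambda: _default_genes()[0])
    signature: Sequence[str] = field(default_factory=lambda: _default_genes()[1])
    cin_fraction: float = 0.25
    effect_log2fc: float = 3.0
    noise_sd: float = 0.5
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    baseline_hazard: float = 0.02
    log_hazard_per_score_unit: float = 0.3
    censor_time: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        _check_prob(self.cin_fraction, "cin_fraction")
        if len(self.signature) == 0:
            raise ValueError("signature gene set must be non-empty")
        if not set(self.signature) <= set(self.genes):
            raise ValueError("signature must be a subset of genes")
        if self.library_size_range[0] <= 0:
            raise ValueError("library sizes must be > 0")
        if self.n_tumors < 1 or self.n_normals < 0:
            raise ValueError("invalid cohort sizes")


def generate_expression_cohort(
    spec: ExpressionCohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate counts, sample annotations and survival records.

    Counts are Poisson draws from per-sample log-normal rates scaled to
    the sample library size; tumors in the planted high-CIN cluster have
    their signature genes shifted by ``effect_log2fc`` on the log2 scale.
    Tumor survival is exponential with hazard ``baseline_hazard *
    exp(log_hazard_per_score_unit * true_score)`` and administrative
    censoring at ``censor_time``, where the planted true score is
    ``effect_log2fc`` for high-CIN tumors and 0 otherwise.
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.genes)
    n_genes = len(genes)
    sig_idx = np.array([genes.index(g) for g in spec.signature])

    tumor_ids = [f"CCA{i + 1:03d}" for i in range(spec.n_tumors)]
    normal_ids = [f"NORM{i + 1:02d}" for i in range(spec.n_normals)]
    samples = tumor_ids + normal_ids

    n_cin = int(round(spec.cin_fraction * spec.n_tumors))
    cin_members = rng.choice(spec.n_tumors, size=n_cin, replace=False)
    is_cin = np.zeros(spec.n_tumors, dtype=bool)
    is_cin[cin_members] = True

    base_log2 = rng.normal(5.0, 2.0, size=n_genes)  # per-gene baseline abundance
    counts = np.empty((n_genes, len(samples)), dtype=np.int64)
    lib_sizes = rng.integers(
        spec.library_size_range[0], spec.library_size_range[1] + 1, size=len(samples)
    )
    for j, _sample in enumerate(samples):
        log2_expr = base_log2 + rng.normal(0.0, spec.noise_sd, size=n_genes)
        if j < spec.n_tumors and is_cin[j]:
            log2_expr[sig_idx] += spec.effect_log2fc
        rates = np.exp2(log2_expr)
        probs = rates / rates.sum()
        counts[:, j] = rng.poisson(lib_sizes[j] * probs)

    matrix = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)
    annotations = pd.DataFrame(
        {
            "sample_id": samples,
            "group": ["tumor"] * spec.n_tumors + ["normal"] * spec.n_normals,
            "planted_cin": list(is_cin) + [False] * spec.n_normals,
            "library_size": lib_sizes,
        }
    )

    true_score = np.where(is_cin, spec.effect_log2fc, 0.0)
    hazard = spec.baseline_hazard * np.exp(spec.log_hazard_per_score_unit * true_score)
    latent = rng.exponential(1.0 / hazard)
    observed = np.minimum(latent, spec.censor_time)
    event = latent <= spec.censor_time
    survival = pd.DataFrame(
        {
            "sample_id": tumor_ids,
            "time": observed,
            "event": event,
        }
    )
    return matrix, annotations, survival


# --------------------------------------------------------------------------
# qPCR knockdown plates
# --------------------------------------------------------------------------

CONDITIONS = ("scrambled", "siYAP", "siTAZ", "siYAP+siTAZ")


def default_knockdown_fractions() -> dict[tuple[str, str], float]:
    """Planted residual-expression fractions for the default plate.

    Direct YAP/TAZ target genes (CYR61, ANKRD1) respond to single and
    combined silencing; CIN-signature genes respond only to combined
    silencing; each siRNA ablates its own transcript.
    """
    fractions: dict[tuple[str, str], float] = {}
    direct = ("CYR61", "ANKRD1")
    cin = ("AURKA", "AURKB", "CCNB1", "CCNB2", "FOXM1", "TOP2A", "TTK")
    for gene in ("YAP", "TAZ") + direct + cin:
        fractions[(gene, "scrambled")] = 1.0
    for gene, cond in (("YAP", "siYAP"), ("TAZ", "siTAZ")):
        fractions[(gene, cond)] = 0.15
        fractions[(gene, "siYAP+siTAZ")] = 0.15
    fractions[("YAP", "siTAZ")] = 1.0
    fractions[("TAZ", "siYAP")] = 1.0
    for gene in direct:
        fractions[(gene, "siYAP")] = 0.5
        fractions[(gene, "siTAZ")] = 0.5
        fractions[(gene, "siYAP+siTAZ")] = 0.25
    for gene in cin:
        fractions[(gene, "siYAP")] = 0.9
        fractions[(gene, "siTAZ")] = 0.9
        fractions[(gene, "siYAP+siTAZ")] = 0.4
    return fractions


@dataclass
class KnockdownPlateSpec:
    target_genes: Sequence[str] = (
        "YAP", "TAZ", "CYR61", "ANKRD1",
        "AURKA", "AURKB", "CCNB1", "CCNB2", "FOXM1", "TOP2A", "TTK",
    )
    conditions: Sequence[str] = CONDITIONS
    knockdown_fraction: Mapping[tuple[str, str], float] = field(
        default_factory=default_knockdown_fractions
    )
    reference_gene: str = "B2M"
    reference_gene_ct: float = 18.0
    target_baseline_ct: float = 24.0
    replicate_n: int = 3
    ct_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicate_n < 2:
            raise ValueError("replicate_n must be >= 2")
        for (gene, cond), f in self.knockdown_fraction.items():
            if not 0 < f <= 1:
                raise ValueError(
                    f"residual fraction for ({gene}, {cond}) must be in (0, 1], got {f}"
                )
        for gene in self.target_genes:
            key = (gene, "scrambled")
            if key in self.knockdown_fraction and self.knockdown_fraction[key] != 1.0:
                raise ValueError("scrambled residual fraction must be 1")


def generate_knockdown_plate(spec: KnockdownPlateSpec) -> pd.DataFrame:
    """Simulate a Ct table for an siRNA plate.

    A residual fraction ``f`` raises the target Ct by ``-log2(f)``
    cycles over its scrambled baseline; the reference gene Ct is
    condition independent up to noise.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for condition in spec.conditions:
        for gene in spec.target_genes:
            fraction = spec.knockdown_fraction.get((gene, condition), 1.0)
            true_ct = spec.target_baseline_ct - np.log2(fraction)
            for rep in range(1, spec.replicate_n + 1):
                rows.append(
                    {
                        "condition": condition,
                        "gene": gene,
                        "replicate": rep,
                        "ct": true_ct + rng.normal(0.0, spec.ct_noise_sd),
                    }
                )
        for rep in range(1, spec.replicate_n + 1):
            rows.append(
                {
                    "condition": condition,
                    "gene": spec.reference_gene,
                    "replicate": rep,
                    "ct": spec.reference_gene_ct + rng.normal(0.0, spec.ct_noise_sd),
                }
            )
    return pd.DataFrame(rows)
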