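"""Synthetic multiplexed-imaging cohorts with known spatial structure.

The generator emulates the statistical shape of a tissue-microarray
immunotherapy cohort: two response arms x two timepoints, a handful of
patients per arm, two or three 0.6 mm circular cores (spots) per patient and
timepoint, and one to two thousand segmented cells per core. Cell types are
drawn from a configurable vocabulary; pairwise spatial attraction between a
source type and an anchor type is injected with a single interpretable
strength parameter, and marker intensities / cell sizes follow per-type
lognormal models with multiplicative tumor-vs-reactive fold changes.

Attraction model
----------------
Anchor-type cells are placed uniformly in the disc. Each cell of a source
type with attraction strengths ``theta_a`` toward anchors ``a`` picks, with
probability ``theta_a / (1 + sum(theta))``, a uniformly random anchor cell
and lands at a displacement with planar density proportional to
``exp(-d / lambda)`` (distance ~ Gamma(2, lambda), uniform angle, rejected
back into the disc); with the remaining probability
``1 / (1 + sum(theta))`` it is placed uniformly. ``theta = 0`` therefore
reduces *exactly* to complete spatial randomness — the property the null-
calibration tests rely on. This is a sampling recipe, not a Gibbs process:
it trades physical realism for an exact null and a monotone, interpretable
strength knob.

Determinism: every random stream is derived from the root seed plus a stable
CRC32 hash of the entity (spot id, stream tag), so any subset of spots is
reproducible on its own.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CellTable, ExpressionMatrix, GROUPS, TIMEPOINTS

# default vocabulary: the minimum needed to exercise every pipeline stage
DEFAULT_TYPES = (
    "reactive CD4 T",
    "PD-1+ CD4 T",
    "tumor",
    "Treg",
    "CD8 T",
    "M1 macrophage",
    "other",
)

DEFAULT_PROPORTIONS = {
    "reactive CD4 T": 0.15,
    "PD-1+ CD4 T": 0.05,
    "tumor": 0.30,
    "Treg": 0.08,
    "CD8 T": 0.12,
    "M1 macrophage": 0.10,
    "other": 0.20,
}

# tumor-vs-reactive-CD4 marker fold changes used as generative defaults
DEFAULT_FOLD_CHANGES = {"CD7": 0.26, "CD30": 1.40, "CD25": 3.20, "Ki-67": 5.73}


class ConfigError(ValueError):
    """Simulation configuration is internally inconsistent."""


@dataclass
class ExpressionModel:
    """Sparse linear dependence of (log-scale) expression on spot covariates.

    ``true_support`` maps gene symbol -> (covariate, coefficient) with
    covariate one of ``log_tumor_frequency`` (natural log of tumor cell
    percentage + 1 percentage-point pseudo-count) and ``log_spatial_score``.
    ``signature_shifts`` adds group/timepoint mean shifts to named gene sets,
    emulating treatment-responsive signatures.
    """

    n_genes: int = 300
    true_support: dict[str, tuple[str, float]] = field(default_factory=dict)
    noise_sd: float = 0.5
    baseline_mean: float = 5.0
    baseline_sd: float = 1.5
    signature_shifts: dict[str, tuple[tuple[str, ...], dict[tuple[str, str], float]]] = field(
        default_factory=dict
    )

    def gene_universe(self) -> list[str]:
        named = list(self.true_support)
        for genes, _ in self.signature_shifts.values():
            named.extend(g for g in genes if g not in named)
        auto = [f"G{i:04d}" for i in range(self.n_genes)]
        # named genes occupy the head of the universe
        extra = [g for g in auto if g not in named]
        universe = named + extra
        return universe[: max(self.n_genes, len(named))]


@dataclass
class SimulationConfig:
    """All generative parameters of a synthetic cohort."""

    n_patients_per_arm: int = 7
    spots_per_patient: int = 2  # per timepoint
    cells_per_spot: int = 1000
    spot_radius: float = 300.0  # core radius in pixels (0.6 mm diameter core)
    type_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    # (source_type, anchor_type) -> (theta >= 0, lambda > 0)
    attraction: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    # optional per-(group, timepoint) replacement of the attraction map,
    # so one cohort encodes distinct spatial phenotypes per arm
    group_attraction: dict[tuple[str, str], dict[tuple[str, str], tuple[float, float]]] = field(
        default_factory=dict
    )
    marker_baseline: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {m: (np.log(50.0), 0.5) for m in DEFAULT_FOLD_CHANGES}
    )
    fold_change_factors: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FOLD_CHANGES)
    )
    tumor_label: str = "tumor"
    reactive_label: str = "reactive CD4 T"
    size_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"tumor": (np.log(150.0), 0.3), "default": (np.log(80.0), 0.3)}
    )
    expression_model: ExpressionModel = field(default_factory=ExpressionModel)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.type_proportions.values())
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ConfigError(f"type_proportions sum to {total}, expected 1")
        maps = [self.attraction, *self.group_attraction.values()]
        for amap in maps:
            sources = {s for (s, _a), (th, _l) in amap.items() if th > 0}
            for (src, anc), (theta, lam) in amap.items():
                if theta > 0 and anc in sources:
                    raise ConfigError(
                        f"type {anc!r} cannot be both an attraction source and anchor"
                    )
                for t in (src, anc):
                    if t not in self.type_proportions:
                        raise ConfigError(
                            f"attraction references type {t!r} absent from proportions"
                        )
                if theta < 0:
                    raise ConfigError("attraction strength theta must be >= 0")
                if lam <= 0:
                    raise ConfigError("attraction length-scale lambda must be > 0")
        if self.expression_model.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for m, f in self.fold_change_factors.items():
            if f <= 0:
                raise ConfigError(f"fold-change factor for {m!r} must be > 0")


def _child_rng(seed: int, *tags: object) -> np.random.Generator:
    """Stable per-entity stream: CRC32 of the repr of each tag."""
    entropy = [seed & 0x7FFFFFFF] + [
        zlib.crc32(repr(t).encode()) & 0xFFFFFFFF for t in tags
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def responder_cohort_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Cohort whose spatial phenotypes mirror the biomarker hypothesis:
    effector PD-1+ CD4 T cells attracted to tumor cells in responders
    (low SpatialScore) and to Tregs in nonresponders (high SpatialScore),
    strengthened post-treatment in responders."""
    lam = 20.0
    ga = {
        ("responder", "pre"): {("PD-1+ CD4 T", "tumor"): (2.0, lam)},
        ("responder", "post"): {("PD-1+ CD4 T", "tumor"): (4.0, lam)},
        ("nonresponder", "pre"): {("PD-1+ CD4 T", "Treg"): (2.0, lam)},
        ("nonresponder", "post"): {("PD-1+ CD4 T", "Treg"): (2.0, lam)},
    }
    return SimulationConfig(seed=seed, group_attraction=ga, **overrides)


# ---------------------------------------------------------------------------
# spatial placement


def _uniform_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    phi = rng.random(n) * 2 * np.pi
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def _place_spot(
    rng: np.random.Generator,
    types: np.ndarray,
    radius: float,
    attraction: Mapping[tuple[str, str], tuple[float, float]],
) -> np.ndarray:
    """Coordinates for one spot; anchors first, then attracted sources."""
    n = len(types)
    xy = np.empty((n, 2))
    by_source: dict[str, list[tuple[str, float, float]]] = {}
    for (src, anc), (theta, lam) in attraction.items():
        if theta > 0:
            by_source.setdefault(src, []).append((anc, theta, lam))

    is_source = np.isin(types, list(by_source))
    idx_free = np.flatnonzero(~is_source)
    xy[idx_free] = _uniform_disc(rng, len(idx_free), radius)

    for src, anchors in by_source.items():
        idx_src = np.flatnonzero(types == src)
        if len(idx_src) == 0:
            continue
        thetas = np.array([a[1] for a in anchors])
        weights = np.concatenate([[1.0], thetas]) / (1.0 + thetas.sum())
        component = rng.choice(len(weights), size=len(idx_src), p=weights)
        xy[idx_src] = _uniform_disc(rng, len(idx_src), radius)  # component 0
        for ci, (anc, _theta, lam) in enumerate(anchors, start=1):
            anchor_xy = xy[np.flatnonzero(types == anc)]
            sel = idx_src[component == ci]
            if len(sel) == 0:
                continue
            if len(anchor_xy) == 0:  # no anchors landed in this spot
                xy[sel] = _uniform_disc(rng, len(sel), radius)
                continue
            for i in sel:
                centre = anchor_xy[rng.integers(len(anchor_xy))]
                for _ in range(200):  # reject displacements leaving the core
                    d = rng.gamma(2.0, lam)
                    phi = rng.random() * 2 * np.pi
                    p = centre + [d * np.cos(phi), d * np.sin(phi)]
                    if p[0] ** 2 + p[1] ** 2 <= radius**2:
                        xy[i] = p
                        break
                else:
                    xy[i] = _uniform_disc(rng, 1, radius)[0]
    return xy


def _spot_cells(
    config: SimulationConfig,
    spot_id: str,
    patient_id: str,
    group: str,
    timepoint: str,
    n_cells: int | None = None,
) -> pd.DataFrame:
    types_order = list(config.type_proportions)
    probs = np.array([config.type_proportions[t] for t in types_order])
    n = n_cells if n_cells is not None else config.cells_per_spot

    rng = _child_rng(config.seed, "spot", spot_id)
    types = np.array(types_order)[rng.choice(len(types_order), size=n, p=probs)]
    attraction = config.group_attraction.get((group, timepoint), config.attraction)
    xy = _place_spot(rng, types, config.spot_radius, attraction)

    rng_m = _child_rng(config.seed, "markers", spot_id)
    markers = {}
    for m, (mu, sigma) in config.marker_baseline.items():
        vals = rng_m.lognormal(mu, sigma, size=n)
        factor = config.fold_change_factors.get(m, 1.0)
        vals = np.where(types == config.tumor_label, vals * factor, vals)
        markers[m] = vals

    rng_s = _child_rng(config.seed, "sizes", spot_id)
    default_sz = config.size_model.get("default", (np.log(80.0), 0.3))
    sizes = np.empty(n)
    for t in types_order:
        mu, sigma = config.size_model.get(t, default_sz)
        mask = types == t
        sizes[mask] = rng_s.lognormal(mu, sigma, size=mask.sum())

    return pd.DataFrame(
        {
            "cell_id": [f"{spot_id}_c{i:05d}" for i in range(n)],
            "spot_id": spot_id,
            "patient_id": patient_id,
            "group": group,
            "timepoint": timepoint,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "cell_type": types,
            "size": sizes,
            **markers,
        }
    )


def simulate_cohort(config: SimulationConfig) -> CellTable:
    """Full two-arm, two-timepoint cohort; deterministic given config.seed."""
    frames = []
    for group in GROUPS:
        prefix = "R" if group == "responder" else "N"
        for p in range(1, config.n_patients_per_arm + 1):
            patient = f"{prefix}{p:02d}"
            for tp in TIMEPOINTS:
                for s in range(1, config.spots_per_patient + 1):
                    spot = f"{patient}_{tp}_s{s}"
                    frames.append(_spot_cells(config, spot, patient, group, tp))
    df = pd.concat(frames, ignore_index=True)
    return CellTable(
        df,
        markers=tuple(config.marker_baseline),
        cell_types=tuple(config.type_proportions),
    )


def simulate_spots(
    config: SimulationConfig,
    n_spots: int,
    group: str = "responder",
    timepoint: str = "pre",
    label: str = "S",
) -> CellTable:
    """Flat batch of i.i.d. spots (one synthetic patient per spot); the
    workhorse for calibration and monotonicity experiments."""
    frames = [
        _spot_cells(
            config, f"{label}{i:04d}", f"P_{label}{i:04d}", group, timepoint
        )
        for i in range(n_spots)
    ]
    df = pd.concat(frames, ignore_index=True)
    return CellTable(
        df,
        markers=tuple(config.marker_baseline),
        cell_types=tuple(config.type_proportions),
    )


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    config: SimulationConfig,
    cells: CellTable,
    spot_scores: Mapping[str, float] | pd.Series,
) -> ExpressionMatrix:
    """Log-scale expression per spot with known sparse covariate dependence.

    gene(g, s) = baseline(g) + coef(g) * covariate(s) + shift(g, arm(s))
                 + Normal(0, noise_sd)

    Covariates are the natural-log tumor-cell percentage (+1 percentage-point
    pseudo-count) and the natural-log per-spot SpatialScore. Returned in
    ``log2_TPM`` state: values are already on the normalised log scale the
    downstream models consume.
    """
    model = config.expression_model
    spots = cells.spots
    missing = [s for s in spots if s not in spot_scores]
    if missing:
        raise ConfigError(f"spot_scores missing spots: {missing[:5]}")

    universe = model.gene_universe()
    gene_pos = {g: i for i, g in enumerate(universe)}
    for g in model.true_support:
        if g not in gene_pos:
            raise ConfigError(f"support gene {g!r} not in gene universe")

    meta = cells.spot_metadata()
    tumor_pct = (
        cells.df.groupby("spot_id")["cell_type"]
        .apply(lambda s: 100.0 * (s == config.tumor_label).mean())
        .reindex(spots)
    )
    cov = {
        "log_tumor_frequency": np.log(tumor_pct.to_numpy() + 1.0),
        "log_spatial_score": np.log(
            np.array([float(spot_scores[s]) for s in spots])
        ),
    }

    rng_base = _child_rng(config.seed, "expr-baseline")
    baseline = rng_base.normal(model.baseline_mean, model.baseline_sd, len(universe))

    vals = np.tile(baseline[:, None], (1, len(spots)))
    for g, (cname, coef) in model.true_support.items():
        if cname not in cov:
            raise ConfigError(f"unknown covariate {cname!r} for gene {g!r}")
        vals[gene_pos[g]] += coef * cov[cname]

    for _name, (genes, shifts) in model.signature_shifts.items():
        for g in genes:
            if g not in gene_pos:
                raise ConfigError(f"signature gene {g!r} not in gene universe")
        for j, s in enumerate(spots):
            key = (meta.loc[s, "group"], meta.loc[s, "timepoint"])
            delta = shifts.get(key, 0.0)
            if delta:
                for g in genes:
                    vals[gene_pos[g], j] += delta

    if model.noise_sd > 0:
        rng_noise = _child_rng(config.seed, "expr-noise")
        vals = vals + rng_noise.normal(0.0, model.noise_sd, vals.shape)

    return ExpressionMatrix(
        pd.DataFrame(vals, index=universe, columns=spots),
        transform_state="log2_TPM",
    )


# ---------------------------------------------------------------------------
# planted-region fixture for neighborhood recovery


def planted_neighborhood_tissue(
    n_regions: int,
    region_compositions: Sequence[Mapping[str, float]],
    cells_per_region: int,
    seed: int,
    region_radius: float = 150.0,
) -> tuple[CellTable, np.ndarray]:
    """Disjoint uniformly-populated discs, each with its own composition.

    Ground truth for cellular-neighborhood recovery: windows never have to
    cross regions because discs are separated by two radii of clear margin.
    Returns the table and per-cell true region labels.
    """
    if n_regions < 2:
        raise ConfigError("need at least 2 regions")
    if len(region_compositions) != n_regions:
        raise ConfigError("one composition per region required")
    comps = [dict(c) for c in region_compositions]
    for c in comps:
        if not np.isclose(sum(c.values()), 1.0, atol=1e-8):
            raise ConfigError("each composition must sum to 1")
    for i in range(n_regions):
        for j in range(i + 1, n_regions):
            if comps[i] == comps[j]:
                import warnings

                warnings.warn(
                    "identical region compositions: recovery is not identifiable"
                )

    rng = _child_rng(seed, "planted")
    frames, truth = [], []
    all_types = sorted({t for c in comps for t in c})
    for r, comp in enumerate(comps):
        centre = np.array([r * 4.0 * region_radius, 0.0])
        xy = _uniform_disc(rng, cells_per_region, region_radius) + centre
        types_order = list(comp)
        probs = np.array([comp[t] for t in types_order])
        types = np.array(types_order)[
            rng.choice(len(types_order), size=cells_per_region, p=probs)
        ]
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": [f"r{r}_c{i:05d}" for i in range(cells_per_region)],
                    "spot_id": "planted",
                    "patient_id": "P0",
                    "group": "responder",
                    "timepoint": "pre",
                    "x": xy[:, 0],
                    "y": xy[:, 1],
                    "cell_type": types,
                    "size": 80.0,
                }
            )
        )
        truth.append(np.full(cells_per_region, r))
    table = CellTable(
        pd.concat(frames, ignore_index=True), markers=(), cell_types=tuple(all_types)
    )
    return table, np.concatenate(truth)
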