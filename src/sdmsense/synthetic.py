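"""Virtual-species study system with known truth.

Everything the real study obtained from portals and climate archives is
generated here instead, with the truth in hand: spatially autocorrelated
covariate surfaces (standing in for bioclimatic layers), a virtual species
whose suitability is a known Gaussian function of the covariates, a
"future" covariate stack shifted to mimic climate change, presence-only
occurrence samples with configurable spatial clumping (observer-effort
bias), and the species' true range standing in for a published range map.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .environment import EnvStack, GridSpec
from .exceptions import SamplingError
from .evaluation import BinaryRange
from .maxent import SuitabilitySurface
from .occurrences import OccurrenceRecord, OccurrenceSet

__all__ = [
    "VirtualSpeciesSpec",
    "SamplingBiasSpec",
    "generate_env_stack",
    "generate_future_stack",
    "true_suitability",
    "sample_occurrences",
]


@dataclass(frozen=True)
class VirtualSpeciesSpec:
    """A species with a Gaussian niche in covariate space.

    True suitability at a cell with standardized covariates z is

        s(z) = max_suitability · exp(−Σ_k (z_k − μ_k)² / (2 σ_k²));

    a breadth of ``inf`` makes a covariate a pure nuisance layer the
    species does not respond to.  The true range is the set of cells with
    s(z) ≥ occupancy_threshold.
    """

    name: str
    optima: tuple[float, ...]
    breadths: tuple[float, ...]
    max_suitability: float = 1.0
    occupancy_threshold: float = 0.3

    def __post_init__(self) -> None:
        if len(self.optima) != len(self.breadths):
            raise ValueError("optima and breadths must have equal length")
        if any(not b > 0 for b in self.breadths):
            raise ValueError("niche breadths must be positive")
        if not 0.0 < self.max_suitability <= 1.0:
            raise ValueError("max_suitability must lie in (0, 1]")
        if not 0.0 < self.occupancy_threshold < 1.0:
            raise ValueError("occupancy_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class SamplingBiasSpec:
    """Observer-effort model for occurrence sampling.

    ``uniform`` effort is flat; ``clustered`` effort concentrates a
    fraction ``cluster_weight`` of the effort on Gaussian bumps (sd
    ``cluster_sd`` in cell units) around ``n_clusters`` random centers,
    mimicking the clumped coverage of public occurrence portals.
    """

    mode: str = "uniform"  # "uniform" | "clustered"
    n_clusters: int = 5
    cluster_sd: float = 5.0
    cluster_weight: float = 0.85

    def __post_init__(self) -> None:
        if self.mode not in ("uniform", "clustered"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")
        if self.mode == "clustered" and self.n_clusters < 1:
            raise ValueError("clustered mode needs at least one cluster")
        if not 0.0 <= self.cluster_weight <= 1.0:
            raise ValueError("cluster_weight must lie in [0, 1]")


def generate_env_stack(
    grid: GridSpec, n_layers: int, autocorr_length: float, seed: int
) -> EnvStack:
    """Smoothed Gaussian random fields, standardized per layer.

    Each layer is white noise convolved with a Gaussian kernel whose sd is
    ``autocorr_length`` cells (0 means no smoothing), then rescaled to mean
    0 and variance 1 over the valid cells.  Deterministic given ``seed``.
    """
    if n_layers < 1:
        raise ValueError("need at least one layer")
    rng = np.random.default_rng(seed)
    layers = []
    for _ in range(n_layers):
        noise = rng.standard_normal(grid.shape)
        if autocorr_length > 0:
            noise = gaussian_filter(noise, sigma=autocorr_length, mode="reflect")
        noise = (noise - noise.mean()) / noise.std()
        layers.append(noise)
    values = np.stack(layers)
    return EnvStack(
        grid=grid,
        layer_names=[f"env{i + 1}" for i in range(n_layers)],
        values=values,
        valid_mask=np.ones(grid.shape, dtype=bool),
    )


def generate_future_stack(
    current: EnvStack, shifts, gradient_axis: str | None = None
) -> EnvStack:
    """Shift each layer by a constant offset to emulate a changed climate.

    With ``gradient_axis="north-south"`` the offset is scaled linearly so
    cell centers at the north edge receive ≈ 2× the offset and the south
    edge ≈ 0 (a poleward change gradient); the map-mean shift stays equal
    to the offset.
    """
    shifts = np.asarray(shifts, dtype=float)
    if shifts.size != current.n_layers:
        raise ValueError("one shift per layer is required")
    if gradient_axis not in (None, "none", "north-south"):
        raise ValueError(f"unknown gradient_axis {gradient_axis!r}")
    n_rows = current.grid.n_rows
    if gradient_axis == "north-south":
        rows = np.arange(n_rows)
        ramp = 2.0 * (1.0 - (rows + 0.5) / n_rows)  # ≈2 at north edge, ≈0 at south
        offset = shifts[:, None, None] * ramp[None, :, None]
    else:
        offset = shifts[:, None, None]
    values = current.values + offset
    return EnvStack(
        grid=current.grid,
        layer_names=list(current.layer_names),
        values=np.where(current.valid_mask[None], values, np.nan),
        valid_mask=current.valid_mask.copy(),
    )


def true_suitability(
    spec: VirtualSpeciesSpec, stack: EnvStack
) -> tuple[SuitabilitySurface, BinaryRange]:
    """Closed-form suitability surface and true range of a virtual species.

    The returned :class:`BinaryRange` (suitability ≥ occupancy_threshold)
    is the reference range that stands in for a published range map.
    """
    if len(spec.optima) != stack.n_layers:
        raise ValueError("species spec dimensionality does not match the stack")
    expo = np.zeros(stack.grid.shape)
    for k in range(stack.n_layers):
        sigma = spec.breadths[k]
        if math.isinf(sigma):
            continue
        z = stack.values[k]
        expo += (z - spec.optima[k]) ** 2 / (2.0 * sigma**2)
    suit = spec.max_suitability * np.exp(-expo)
    suit = np.where(stack.valid_mask, suit, np.nan)
    vals = suit[stack.valid_mask]
    surface = SuitabilitySurface(
        grid=stack.grid,
        probability=suit,
        valid_mask=stack.valid_mask.copy(),
        max_probability=float(np.max(vals)),
    )
    present = np.zeros(stack.grid.shape, dtype=bool)
    present[stack.valid_mask] = vals >= spec.occupancy_threshold
    rng_range = BinaryRange(
        grid=stack.grid, present=present, threshold_used=spec.occupancy_threshold
    )
    return surface, rng_range


def sample_occurrences(
    truth: SuitabilitySurface,
    n: int,
    bias: SamplingBiasSpec,
    seed: int,
    species: str = "virtual",
    effort_mask: np.ndarray | None = None,
) -> OccurrenceSet:
    """Draw presence-only occurrence records from a true suitability surface.

    Cells are drawn (with replacement) with probability proportional to
    suitability × observer effort; each draw is then placed uniformly
    within its cell.  ``effort_mask`` restricts effort to a surveyed
    sub-region (cells outside it receive zero effort regardless of mode),
    emulating real occurrence archives that cover only part of a species'
    range.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("need at least one occurrence")
    grid = truth.grid
    allowed = truth.valid_mask.copy()
    if effort_mask is not None:
        allowed &= np.asarray(effort_mask, dtype=bool)
    rr, cc = np.nonzero(allowed)
    if rr.size == 0:
        raise SamplingError("no cells available for sampling")
    suit = truth.probability[rr, cc]

    rng = np.random.default_rng(seed)
    if bias.mode == "uniform":
        effort = np.ones(rr.size)
    else:
        centers = rng.choice(rr.size, size=bias.n_clusters, replace=True)
        # squared distances in cell units from each allowed cell to each center
        d2 = (rr[:, None] - rr[centers][None, :]) ** 2 + (
            cc[:, None] - cc[centers][None, :]
        ) ** 2
        bumps = np.exp(-d2 / (2.0 * bias.cluster_sd**2)).sum(axis=1)
        total = bumps.sum()
        if total <= 0:
            bumps = np.ones(rr.size)
            total = float(rr.size)
        effort = bias.cluster_weight * bumps / total + (
            1.0 - bias.cluster_weight
        ) * np.ones(rr.size) / rr.size

    p = suit * effort
    total = p.sum()
    if not total > 0:
        raise SamplingError("suitability × effort is zero everywhere; cannot sample")
    p = p / total
    draws = rng.choice(rr.size, size=n, replace=True, p=p)
    jitter = rng.random((n, 2))
    xs = grid.x_origin + (cc[draws] + jitter[:, 0]) * grid.cell_size
    ys = grid.y_origin - (rr[draws] + jitter[:, 1]) * grid.cell_size
    records = [
        OccurrenceRecord(species=species, x=float(x), y=float(y)) for x, y in zip(xs, ys)
    ]
    label = "biased" if bias.mode == "clustered" else "raw"
    return OccurrenceSet(
        species=species,
        records=records,
        provenance=f"synthetic(seed={seed}, mode={bias.mode})",
        treatment_label=label,
    )
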