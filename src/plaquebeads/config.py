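"""Parameter objects shared across the pipeline.

All physical quantities are in micrometres (µm) unless the name says
otherwise; intensities are in arbitrary detector units.  Every container
validates its invariants on construction so that errors surface at the
configuration stage rather than deep inside a pipeline run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Tuple

__all__ = [
    "ConfigurationError",
    "CapacityError",
    "CHANNELS",
    "BEAD_CHANNEL",
    "NoiseModel",
    "BackgroundModel",
    "SceneConfig",
    "BeadSpec",
    "DetectionParams",
    "GateParams",
    "FlowComposition",
    "GroupSpec",
    "Effect",
    "CohortSpec",
]


class ConfigurationError(ValueError):
    """A parameter object violates one of its invariants."""


class CapacityError(RuntimeError):
    """The scene cannot accommodate the requested content (e.g. too many
    beads for the available area at the required minimum separation)."""


#: Detection bands of the three-channel multiphoton acquisition:
#: collagen second-harmonic generation, the bead/elastin autofluorescence
#: band, and the neutral-lipid (oil-red-O) band.
CHANNELS: Tuple[str, str, str] = ("shg_380_440", "green_490_530", "red_530_650")

#: Channel into which fluorescent beads are rendered and in which they are
#: counted (490–530 nm emission).
BEAD_CHANNEL = "green_490_530"


@dataclass(frozen=True)
class NoiseModel:
    """Photon-limited detector noise: Poisson shot noise plus Gaussian read
    noise.

    ``poisson_gain`` is the number of detected photons per intensity unit;
    the recorded value is ``Poisson(gain * signal) / gain``.  A gain of 0
    disables shot noise.  ``gaussian_sigma`` is the read-noise standard
    deviation in intensity units; 0 disables it.
    """

    gaussian_sigma: float = 2.0
    poisson_gain: float = 5.0

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0 or self.poisson_gain < 0:
            raise ConfigurationError("noise parameters must be >= 0")

    @property
    def is_noiseless(self) -> bool:
        return self.gaussian_sigma == 0 and self.poisson_gain == 0


@dataclass(frozen=True)
class BackgroundModel:
    """Amplitudes of the phenomenological tissue textures, per channel.

    The collagen channel carries anisotropic fibre streaks, the green
    channel a diffuse autofluorescence floor with slow spatial variation,
    and the red channel bright lipid blobs.  Setting every amplitude to 0
    yields empty tissue.
    """

    fiber_amplitude: float = 40.0
    fiber_sigma_um: Tuple[float, float] = (0.5, 4.0)  # (across, along) fibre
    autofluor_mean: float = 30.0
    autofluor_variation: float = 8.0
    lipid_blob_count: int = 12
    lipid_blob_sigma_um: float = 4.0
    lipid_amplitude: float = 50.0

    def __post_init__(self) -> None:
        if min(self.fiber_amplitude, self.autofluor_mean,
               self.autofluor_variation, self.lipid_amplitude) < 0:
            raise ConfigurationError("background amplitudes must be >= 0")
        if self.lipid_blob_count < 0:
            raise ConfigurationError("lipid_blob_count must be >= 0")


@dataclass(frozen=True)
class SceneConfig:
    """Physical geometry and texture of one simulated specimen volume.

    The voxel grid is ``ceil(extent / step)`` along each axis; voxel
    ``(k, j, i)`` covers the half-open box ``[i*s, (i+1)*s) x ...`` with its
    intensity sampled at the voxel centre.  The default 10 µm axial step and
    the three detection bands follow the tiled-acquisition protocol this
    simulator emulates; the 0.25 µm lateral pixel makes a 1 µm bead span
    about 4 pixels.
    """

    width_um: float = 100.0
    height_um: float = 100.0
    depth_um: float = 230.0
    pixel_size_um: float = 0.25
    z_step_um: float = 10.0
    channels: Tuple[str, ...] = CHANNELS
    background: BackgroundModel = field(default_factory=BackgroundModel)
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if min(self.width_um, self.height_um, self.depth_um) <= 0:
            raise ConfigurationError("scene extents must be > 0")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ConfigurationError("pixel_size_um and z_step_um must be > 0")
        if not self.channels:
            raise ConfigurationError("at least one channel is required")

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        """(nz, ny, nx) voxel counts, each >= 1."""
        return (
            max(1, math.ceil(self.depth_um / self.z_step_um)),
            max(1, math.ceil(self.height_um / self.pixel_size_um)),
            max(1, math.ceil(self.width_um / self.pixel_size_um)),
        )


@dataclass(frozen=True)
class BeadSpec:
    """Rendering model of a 1 µm fluorescent microsphere under the imaging
    point-spread function.

    A bead is a uniform disk of ``diameter_um`` blurred laterally by a
    Gaussian of ``lateral_sigma_um`` and spread axially by a Gaussian of
    ``axial_sigma_um``.  The axial sigma is much larger than the lateral one:
    with a low-NA objective in scattering tissue the bead image is strongly
    elongated along z, which is what makes a single bead visible in at least
    two 10 µm-spaced sections.
    """

    diameter_um: float = 1.0
    peak_intensity: float = 100.0
    lateral_sigma_um: float = 0.3
    axial_sigma_um: float = 6.0

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ConfigurationError("diameter_um must be > 0")
        if self.peak_intensity <= 0:
            raise ConfigurationError("peak_intensity must be > 0")
        if self.axial_sigma_um < self.lateral_sigma_um:
            raise ConfigurationError(
                "axial_sigma_um must be >= lateral_sigma_um (axial elongation)")


@dataclass(frozen=True)
class DetectionParams:
    """Spot-detection settings.

    The diameter bounds select bead-sized objects (0.5–1.5 µm equivalent
    diameter); ``threshold`` is the required brightness above the local
    background, estimated with a median filter of radius
    ``local_background_radius_um``.  The default threshold is a nominal
    value for the simulator's default brightness scale; for any new data
    set it should be re-derived with
    :func:`plaquebeads.detect.calibrate_threshold` against reference counts
    on representative composites.
    """

    min_diameter_um: float = 0.5
    max_diameter_um: float = 1.5
    threshold: float = 15.0
    local_background_radius_um: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.min_diameter_um < self.max_diameter_um):
            raise ConfigurationError(
                "need 0 < min_diameter_um < max_diameter_um")
        if self.threshold < 0:
            raise ConfigurationError("threshold must be >= 0")
        if self.local_background_radius_um <= 0:
            raise ConfigurationError("local_background_radius_um must be > 0")


@dataclass(frozen=True)
class GateParams:
    """Sequential gating cutoffs for the labeling-verification cytometry.

    The live gate is a rectangle in (FSC, SSC); monocytes are CD115-high
    among live cells; Gr1 splits monocytes into classical (high) and
    non-classical (low); FITC marks bead-positive events.
    """

    fsc_range: Tuple[float, float] = (120.0, 400.0)
    ssc_range: Tuple[float, float] = (0.0, 400.0)
    cd115_threshold: float = 500.0
    gr1_threshold: float = 500.0
    fitc_threshold: float = 400.0

    def __post_init__(self) -> None:
        for lo, hi in (self.fsc_range, self.ssc_range):
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ConfigurationError("live gate bounds must be finite, lo < hi")
        for t in (self.cd115_threshold, self.gr1_threshold, self.fitc_threshold):
            if not math.isfinite(t):
                raise ConfigurationError("marker thresholds must be finite")


#: Latent event classes of the simulated blood sample.
FLOW_CLASSES: Tuple[str, ...] = (
    "debris",
    "nonmono_leukocyte",
    "mono_gr1hi",
    "mono_gr1lo",
    "mono_gr1lo_beadpos",
    "mono_gr1hi_beadpos",
)

FLOW_MARKERS: Tuple[str, ...] = ("fsc", "ssc", "cd115", "gr1", "fitc")


def _default_flow_distributions() -> Mapping[str, Mapping[str, Tuple[float, float]]]:
    leuk_scatter = {"fsc": (200.0, 20.0), "ssc": (150.0, 30.0)}
    cd115_neg = {"cd115": (100.0, 50.0)}
    cd115_pos = {"cd115": (1000.0, 100.0)}
    gr1_hi = {"gr1": (1000.0, 100.0)}
    gr1_lo = {"gr1": (100.0, 50.0)}
    fitc_neg = {"fitc": (50.0, 30.0)}
    fitc_pos = {"fitc": (1000.0, 100.0)}
    return {
        "debris": {"fsc": (50.0, 15.0), "ssc": (40.0, 15.0),
                   **cd115_neg, **gr1_lo, **fitc_neg},
        "nonmono_leukocyte": {**leuk_scatter, **cd115_neg, **gr1_hi, **fitc_neg},
        "mono_gr1hi": {**leuk_scatter, **cd115_pos, **gr1_hi, **fitc_neg},
        "mono_gr1lo": {**leuk_scatter, **cd115_pos, **gr1_lo, **fitc_neg},
        "mono_gr1lo_beadpos": {**leuk_scatter, **cd115_pos, **gr1_lo, **fitc_pos},
        "mono_gr1hi_beadpos": {**leuk_scatter, **cd115_pos, **gr1_hi, **fitc_pos},
    }


@dataclass(frozen=True)
class FlowComposition:
    """Composition of a simulated blood sample for gating verification.

    Fractions follow the gating hierarchy: ``live_fraction`` of all events
    are leukocytes, ``monocyte_fraction_of_leukocytes`` of those are
    monocytes, and so on.  Bead-positive events sit in the Gr1-low subset
    unless ``beadpos_fraction_of_gr1hi`` is raised above its default of 0
    (intravenous bead injection labels non-classical monocytes only).
    """

    n_events: int = 10_000
    live_fraction: float = 0.9
    monocyte_fraction_of_leukocytes: float = 0.127
    gr1lo_fraction_of_monocytes: float = 0.5
    beadpos_fraction_of_monocytes: float = 0.058
    beadpos_fraction_of_gr1hi: float = 0.0
    distributions: Mapping[str, Mapping[str, Tuple[float, float]]] = field(
        default_factory=_default_flow_distributions)

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ConfigurationError("n_events must be >= 0")
        fracs = (self.live_fraction, self.monocyte_fraction_of_leukocytes,
                 self.gr1lo_fraction_of_monocytes,
                 self.beadpos_fraction_of_monocytes,
                 self.beadpos_fraction_of_gr1hi)
        if any(not 0 <= f <= 1 for f in fracs):
            raise ConfigurationError("all fractions must lie in [0, 1]")
        if self.beadpos_fraction_of_monocytes > self.gr1lo_fraction_of_monocytes:
            raise ConfigurationError(
                "bead-positive fraction cannot exceed the Gr1-low fraction")
        for cls in FLOW_CLASSES:
            if cls not in self.distributions:
                raise ConfigurationError(f"missing distributions for class {cls!r}")
            for marker in FLOW_MARKERS:
                mu, sigma = self.distributions[cls][marker]
                if sigma <= 0:
                    raise ConfigurationError(
                        f"sigma for {cls}/{marker} must be > 0")
                if not math.isfinite(mu):
                    raise ConfigurationError(f"mean for {cls}/{marker} must be finite")

    def class_probabilities(self) -> "dict[str, float]":
        """Expand the hierarchical fractions into per-class probabilities."""
        live = self.live_fraction
        mono = live * self.monocyte_fraction_of_leukocytes
        bead_lo = mono * self.beadpos_fraction_of_monocytes
        gr1lo = mono * self.gr1lo_fraction_of_monocytes
        gr1hi = mono - gr1lo
        bead_hi = gr1hi * self.beadpos_fraction_of_gr1hi
        return {
            "debris": 1.0 - live,
            "nonmono_leukocyte": live - mono,
            "mono_gr1hi": gr1hi - bead_hi,
            "mono_gr1lo": gr1lo - bead_lo,
            "mono_gr1lo_beadpos": bead_lo,
            "mono_gr1hi_beadpos": bead_hi,
        }


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group: label, number of animals and the mean number
    of beads planted per animal (``None`` if derived from an effect)."""

    label: str
    n_animals: int
    mean_beads: "float | None" = None

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ConfigurationError("n_animals must be >= 1")
        if self.mean_beads is not None and self.mean_beads < 0:
            raise ConfigurationError("mean_beads must be >= 0")


@dataclass(frozen=True)
class Effect:
    """Relation deriving one group's mean bead density from a reference
    group: ``fold_ratio`` (group = value * reference) or
    ``reduction_percent`` (group = (1 - value/100) * reference)."""

    kind: str
    value: float
    group: str
    reference: str

    def __post_init__(self) -> None:
        if self.kind not in ("fold_ratio", "reduction_percent"):
            raise ConfigurationError(f"unknown effect kind {self.kind!r}")
        if self.kind == "fold_ratio" and self.value <= 0:
            raise ConfigurationError("fold_ratio must be > 0")
        if self.kind == "reduction_percent" and not 0 <= self.value <= 100:
            raise ConfigurationError("reduction_percent must lie in [0, 100]")


def _cohort_scene() -> SceneConfig:
    # Desk-scale specimen: one plaque region per animal, 2x2 mosaic.
    return SceneConfig(width_um=60.0, height_um=60.0, depth_um=40.0)


@dataclass(frozen=True)
class CohortSpec:
    """A multi-animal experiment: per-group bead densities (Poisson per
    animal), the shared scene/tiling geometry, and a master seed."""

    groups: Tuple[GroupSpec, ...]
    effects: Tuple[Effect, ...] = ()
    seed: int = 0
    scene: SceneConfig = field(default_factory=_cohort_scene)
    bead: BeadSpec = field(default_factory=BeadSpec)
    grid: Tuple[int, int] = (2, 2)
    overlap_fraction: float = 0.1
    clump_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not self.groups:
            raise ConfigurationError("at least one group is required")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("group labels must be unique")
        for eff in self.effects:
            for lab in (eff.group, eff.reference):
                if lab not in labels:
                    raise ConfigurationError(
                        f"effect references unknown group {lab!r}")
        if not 0 <= self.overlap_fraction < 1:
            raise ConfigurationError("overlap_fraction must lie in [0, 1)")
        if not 0 <= self.clump_fraction <= 1:
            raise ConfigurationError("clump_fraction must lie in [0, 1]")
        # every group must end up with a defined mean
        derived = {e.group for e in self.effects}
        for g in self.groups:
            if g.mean_beads is None and g.label not in derived:
                raise ConfigurationError(
                    f"group {g.label!r} has no mean and no deriving effect")

    def resolved_means(self) -> "dict[str, float]":
        """Group means after applying effect descriptors."""
        means: dict[str, float] = {
            g.label: g.mean_beads for g in self.groups if g.mean_beads is not None
        }
        pending = list(self.effects)
        while pending:
            progressed = False
            for eff in list(pending):
                if eff.reference in means:
                    ref = means[eff.reference]
                    if eff.kind == "fold_ratio":
                        means[eff.group] = eff.value * ref
                    else:
                        means[eff.group] = (1.0 - eff.value / 100.0) * ref
                    pending.remove(eff)
                    progressed = True
            if not progressed:
                raise ConfigurationError(
                    "effect descriptors form an unresolvable cycle")
        return means
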