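"""Parameter-recovery experiments on the synthetic generator.

These drive the full pipeline end to end under the study conditions the
package emulates: tiled three-channel acquisitions with 10% overlap and a
10 µm z-step, cohorts of a few animals per condition, and 10,000-event
labeling-verification tables.  Each experiment plants a known effect —
a 3-fold difference in bead accumulation, a 37% treatment reduction, the
monocyte and bead-positive fractions — and measures how well the pipeline
recovers it, returning both the recovered value and its sampling error.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np

from .config import (
    BeadSpec,
    CohortSpec,
    DetectionParams,
    Effect,
    FlowComposition,
    GateParams,
    GroupSpec,
)
from .detect import calibrate_threshold, sum_projection
from .flow import bead_positive_fraction, gate_live, gate_monocytes, monocyte_fraction
from .mosaic import count_sample
from .stats import one_tailed_t, percent_reduction
from .synthetic import generate_cohort, generate_flow_events, generate_scene, plant_beads, tile_scene

__all__ = [
    "calibrate_detection",
    "fold_change_recovery",
    "reduction_recovery",
    "gating_recovery",
]

#: Threshold grid scanned during calibration (intensity above background).
CALIBRATION_GRID = (8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0, 25.0, 30.0)


def _cohort_scene():
    return CohortSpec(groups=(GroupSpec("x", 1, 0.0),)).scene


def calibrate_detection(seed: int,
                        params: DetectionParams = DetectionParams()
                        ) -> DetectionParams:
    """Calibrate the brightness threshold on two representative samples.

    Mirrors the method's calibration step: one sparse and one dense
    composite (standing in for a day-1 and a day-5 sample) with known bead
    counts serve as the reference, and the threshold minimising the summed
    absolute count error over both is adopted.
    """
    scene_cfg = _cohort_scene()
    projections, references = [], []
    for rep, n in enumerate((20, 60)):
        scene = generate_scene(scene_cfg, seed=seed + rep)
        plant_beads(scene, n, BeadSpec(), clump_fraction=0.05,
                    seed=seed + 100 + rep)
        tiles = tile_scene(scene, 1, 1, 0.0)
        projections.append(
            sum_projection(tiles.tiles[(0, 0)]["green_490_530"]))
        references.append(len(scene.truth))
    threshold = calibrate_threshold(projections, references,
                                    CALIBRATION_GRID, params,
                                    scene_cfg.pixel_size_um)
    return DetectionParams(
        min_diameter_um=params.min_diameter_um,
        max_diameter_um=params.max_diameter_um,
        threshold=threshold,
        local_background_radius_um=params.local_background_radius_um,
    )


def _count_cohorts(spec_seed: int, groups, effects,
                   params: DetectionParams) -> Dict[str, List[int]]:
    counts: Dict[str, List[int]] = {g.label: [] for g in groups}
    cohort = generate_cohort(
        CohortSpec(groups=groups, effects=effects, seed=spec_seed))
    for label, _animal, tiles, _truth in cohort:
        counts[label].append(count_sample(tiles, params))
    return counts


def fold_change_recovery(seed: int, n_seeds: int = 20, n_animals: int = 5,
                         mean_low: float = 20.0, ratio: float = 3.0) -> dict:
    """Recover a planted fold difference in bead accumulation.

    Two cohorts of ``n_animals`` each are planted with per-animal Poisson
    bead counts whose means differ by ``ratio`` (day-5 vs day-1 style),
    counted by the full pipeline, and pooled over ``n_seeds`` replicates.
    Returns the recovered ratio of group means, its delta-method standard
    error, and the pooled one-tailed p-value of the last replicate's
    comparison.
    """
    params = calibrate_detection(seed)
    rng = np.random.default_rng(seed)
    groups = (GroupSpec("day1", n_animals, mean_low),
              GroupSpec("day5", n_animals))
    effects = (Effect("fold_ratio", ratio, group="day5", reference="day1"),)
    day1: List[int] = []
    day5: List[int] = []
    for _ in range(n_seeds):
        counts = _count_cohorts(int(rng.integers(2**31)), groups, effects,
                                params)
        day1.extend(counts["day1"])
        day5.extend(counts["day5"])
    a, b = np.asarray(day5, float), np.asarray(day1, float)
    recovered = a.mean() / b.mean()
    sem_a = a.std(ddof=1) / np.sqrt(len(a))
    sem_b = b.std(ddof=1) / np.sqrt(len(b))
    se = recovered * np.sqrt((sem_a / a.mean()) ** 2 + (sem_b / b.mean()) ** 2)
    return {
        "ratio": float(recovered),
        "se": float(se),
        "planted_ratio": ratio,
        "n_per_group": len(day1),
        "p_value": one_tailed_t(a, b, "greater"),
        "threshold": params.threshold,
    }


def reduction_recovery(seed: int, n_seeds: int = 20, n_animals: int = 3,
                       control_mean: float = 60.0,
                       reduction_percent: float = 37.0) -> dict:
    """Recover a planted treatment reduction in bead accumulation.

    Control and treated cohorts of ``n_animals`` each (statin-style design)
    are planted with treated mean density reduced by ``reduction_percent``,
    counted end to end, and pooled over ``n_seeds`` replicates.  Returns the
    recovered percent reduction with its delta-method standard error.
    """
    params = calibrate_detection(seed)
    rng = np.random.default_rng(seed + 1)
    groups = (GroupSpec("vehicle", n_animals, control_mean),
              GroupSpec("statin", n_animals))
    effects = (Effect("reduction_percent", reduction_percent,
                      group="statin", reference="vehicle"),)
    control: List[int] = []
    treated: List[int] = []
    for _ in range(n_seeds):
        counts = _count_cohorts(int(rng.integers(2**31)), groups, effects,
                                params)
        control.extend(counts["vehicle"])
        treated.extend(counts["statin"])
    recovered, se = percent_reduction(control, treated)
    return {
        "reduction_percent": float(recovered),
        "se": float(se),
        "planted_percent": reduction_percent,
        "n_per_group": len(control),
        "p_value": one_tailed_t(treated, control, "less"),
        "threshold": params.threshold,
    }


def gating_recovery(seed: int, n_events: int = 10_000,
                    n_tables: int = 10) -> dict:
    """Recover the planted monocyte and bead-positive fractions by gating.

    Each replicate table holds ``n_events`` events with 12.7% of leukocytes
    planted as monocytes and 5.8% of monocytes planted bead-positive
    (Gr1-low); the gate chain is applied and the recovered percentages are
    averaged over ``n_tables`` independently seeded tables to suppress
    Monte-Carlo noise.
    """
    comp = FlowComposition(n_events=n_events)
    gates = GateParams()
    rng = np.random.default_rng(seed)
    mono, beadpos = [], []
    n_live_total = n_mono_total = 0
    for _ in range(n_tables):
        events = generate_flow_events(comp, seed=int(rng.integers(2**31)))
        live = gate_live(events, gates)
        monocytes = gate_monocytes(live, gates)
        mono.append(monocyte_fraction(live, gates))
        beadpos.append(bead_positive_fraction(monocytes, gates,
                                              denominator="all_monocytes"))
        n_live_total += len(live)
        n_mono_total += len(monocytes)
    return {
        "monocyte_percent": float(np.mean(mono)),
        "beadpos_percent": float(np.mean(beadpos)),
        "planted_monocyte_percent": 100 * comp.monocyte_fraction_of_leukocytes,
        "planted_beadpos_percent": 100 * comp.beadpos_fraction_of_monocytes,
        "monocyte_se": float(100 * np.sqrt(0.127 * 0.873 / n_live_total)),
        "beadpos_se": float(100 * np.sqrt(0.058 * 0.942 / n_mono_total)),
        "n_events": n_events * n_tables,
    }
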