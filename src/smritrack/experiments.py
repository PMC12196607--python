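"""Study-scale validation experiments on seeded phantom cohorts.

Each function runs one self-contained experiment — biomarker recovery,
interval-classification accuracy, statistical calibration, regression
parameter recovery — and returns plain numbers.  The analysis drivers,
the test suite and the acceptance script all call these; nothing here
hard-codes an expected outcome.

Problem sizes default to a reduced phantom (36³ grid at 3 mm, 10 mm
lesion) so whole batteries run in seconds on one CPU; the full-size
phantom behaves identically, only slower.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np

from .phantom import EvolutionMode, PhantomConfig, make_series, make_timepoint
from .pipeline import classify_timepoint_pair
from .segmentation import segment_timepoint
from .stats import compare_modalities, fit_volume_regression
from .overlap import dice

#: reduced-size phantom used by the validation batteries
BATTERY_PHANTOM = dict(
    grid_shape=(36, 36, 36),
    voxel_spacing_mm=(3.0, 3.0, 3.0),
    brain_semi_axes_mm=(46.0, 50.0, 44.0),
    tumor_center_mm=(-20.0, 4.0, 2.0),
    tumor_radius_mm=10.0,
    coverage_erosion_mm=4.0,
)

EXPECTED_CALL = {
    "STABLE": "STABLE_OR_RESPONSE",
    "RESPONSE": "STABLE_OR_RESPONSE",
    "TRUE_PROGRESSION": "TRUE_PROGRESSION",
    "PSEUDOPROGRESSION": "PSEUDOPROGRESSION",
}


def segmentation_recovery(
    seed: int = 0, n_seeds: int = 20, noise_sd: float = 0.1,
    full_size: bool = True,
) -> dict:
    """Recovery of the planted lesion by the 2X segmentation.

    Noiseless case: exact voxel-for-voxel equality with the planted mask.
    Noisy case (default 10% of NAWM Cho): Dice against the planted mask
    over ``n_seeds`` independent phantoms.
    """
    base = PhantomConfig() if full_size else PhantomConfig(**BATTERY_PHANTOM)

    noiseless = dataclasses.replace(base, noise_sd=0.0, seed=seed)
    tp = make_timepoint(noiseless, -1.0)
    mask, _ = segment_timepoint(tp.cho, tp.naa, nawm=tp.masks["NAWM"],
                                min_component_cc=0.0)
    exact = bool(np.array_equal(mask.values, tp.masks["GROUND_TRUTH"].values))

    dices = []
    for k in range(n_seeds):
        cfg = dataclasses.replace(base, noise_sd=noise_sd, seed=seed + k)
        tp = make_timepoint(cfg, -1.0)
        mask, _ = segment_timepoint(tp.cho, tp.naa, nawm=tp.masks["NAWM"])
        dices.append(dice(mask, tp.masks["GROUND_TRUTH"]))
    return {
        "noiseless_exact": exact,
        "dices": dices,
        "min_dice": float(np.min(dices)),
        "mean_dice": float(np.mean(dices)),
    }


def classify_phantom_series(mode_label: str, seed: int,
                            config: PhantomConfig | None = None,
                            timepoints=(-1.0, 3.0)) -> str:
    """Generate one series, segment every timepoint, classify, majority-vote."""
    cfg = config or PhantomConfig(**BATTERY_PHANTOM, noise_sd=0.1)
    cfg = dataclasses.replace(cfg, seed=seed)
    series = make_series(cfg, EvolutionMode.preset(mode_label), timepoints)
    for tp in series.timepoints:
        tp.masks["CHO_NAA_2X"], _ = segment_timepoint(
            tp.cho, tp.naa, nawm=tp.masks["NAWM"]
        )
    labels = [
        classify_timepoint_pair(e, l)[0].label
        for e, l in zip(series.timepoints[:-1], series.timepoints[1:])
    ]
    values, counts = np.unique(labels, return_counts=True)
    return str(values[np.argmax(counts)])


def classification_accuracy(
    seed: int = 0,
    n_series: int = 200,
    modes: tuple[str, ...] = ("TRUE_PROGRESSION", "PSEUDOPROGRESSION", "STABLE"),
    noise_sd: float = 0.1,
) -> Mapping[str, float]:
    """Fraction of phantom series whose planted mode is recovered."""
    cfg = PhantomConfig(**BATTERY_PHANTOM, noise_sd=noise_sd)
    out = {}
    for mode in modes:
        correct = sum(
            classify_phantom_series(mode, (seed * 9973 + i) % 2**31, cfg)
            == EXPECTED_CALL[mode]
            for i in range(n_series)
        )
        out[mode] = correct / n_series
    return out


def null_fwer(seed: int = 0, reps: int = 2000, n_pairs: int = 20) -> dict:
    """Family-wise rejection rate of the gated two-hypothesis comparison
    under a paired null with no modality difference.

    Both members of each pair share a mean; differences are pure noise.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        base_dsc = rng.uniform(0.1, 0.7, n_pairs)
        dsc_a = np.clip(base_dsc + rng.normal(0, 0.08, n_pairs), 0, 1)
        dsc_b = np.clip(base_dsc + rng.normal(0, 0.08, n_pairs), 0, 1)
        base_hd = rng.uniform(10, 60, n_pairs)
        hd_a = np.abs(base_hd + rng.normal(0, 5, n_pairs))
        hd_b = np.abs(base_hd + rng.normal(0, 5, n_pairs))
        cmp_dsc, cmp_hd = compare_modalities(dsc_a, dsc_b, hd_a, hd_b)
        rejections += cmp_dsc.significant or cmp_hd.significant
    rate = rejections / reps
    mc_se = float(np.sqrt(0.05 * 0.95 / reps))
    return {"fwer": rate, "reps": reps, "mc_se": mc_se}


def regression_recovery(
    seed: int = 0, n_points: int = 200, n_seeds: int = 100,
    true_slope: float = 1.2, target_r: float = 0.9,
) -> dict:
    """Slope / correlation recovery of the volume regression on synthetic
    biomarker-vs-FLAIR volume pairs with a planted linear relation."""
    rng = np.random.default_rng(seed)
    # noise scaled so the planted correlation is target_r
    noise_frac = float(np.sqrt(1.0 / target_r**2 - 1.0))
    slopes, rs = [], []
    for _ in range(n_seeds):
        x = rng.uniform(5.0, 150.0, n_points)
        signal = true_slope * x
        y = signal + rng.normal(0, noise_frac * np.std(signal), n_points)
        fit = fit_volume_regression(x, y)
        slopes.append(fit.slope)
        rs.append(fit.r)
    return {
        "true_slope": true_slope,
        "target_r": target_r,
        "mean_slope": float(np.mean(slopes)),
        "mean_r": float(np.mean(rs)),
        "max_slope_rel_err": float(
            np.max(np.abs(np.asarray(slopes) - true_slope)) / true_slope
        ),
        "max_r_abs_err": float(np.max(np.abs(np.asarray(rs) - target_r))),
        "n_points": n_points,
        "n_seeds": n_seeds,
    }
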