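"""End-to-end validation experiments on synthetic screens.

Each function simulates a study condition with known ground truth,
runs the relevant pipeline stages, and returns the recovered
quantities. They are used by the test suite and by the reproduction
script, and are convenient entry points for exploring how the
estimators behave as conditions change.
"""

from __future__ import annotations

import numpy as np

from . import kinematics, polar, synthetic


def kappa_response_curve(
    kappas=(0.0, 1.0, 4.0, 16.0, 1e6),
    n_cells: int = 120,
    n_fragments: int = 12,
    seed: int = 0,
) -> dict[float, float]:
    """Mean truth-fragment PDS per angular concentration κ.

    The score should respond monotonically: dispersed fragments (κ = 0)
    score near the uniform limit, concentrated ones approach 1.75.
    """
    arms = {
        f"k{i}": synthetic.GolgiDispersionSpec(
            n_fragments=n_fragments, angular_concentration=k
        )
        for i, k in enumerate(kappas)
    }
    screen = synthetic.simulate_screen_truth(arms, n_cells_per_arm=n_cells, seed=seed)
    return {
        k: float(polar.score_cells(screen[f"k{i}"])["pds"].mean())
        for i, k in enumerate(kappas)
    }


def speed_recovery(
    speeds=(0.2, 0.5, 1.0),
    n_frames: int = 30,
    n_carriers: int = 3,
    seed: int = 0,
) -> dict[float, float]:
    """Mean tracked speed per programmed straight-path speed (µm/s).

    Clean (noise-free) videos through the full preprocess → detect →
    link → filter pipeline.
    """
    out = {}
    for i, v in enumerate(speeds):
        tl = synthetic.generate_timelapse(
            [synthetic.CarrierSpec(n_carriers=n_carriers, speed=v)],
            n_frames=n_frames,
            seed=seed * 1000 + i,
        )
        table = kinematics.analyze_timelapse(tl.channels["carrier"], tl.calibration)
        out[v] = float(table["mean_speed_um_s"].mean())
    return out


def depletion_speed_ratio(
    control_speed: float = 0.5,
    effect: float = 0.7,
    n_replicates: int = 3,
    n_frames: int = 25,
    n_carriers: int = 4,
    seed: int = 0,
) -> float:
    """Recovered mean-speed ratio of a depletion arm programmed at
    ``effect`` × control speed, averaged over replicates."""
    ratios = []
    for rep in range(n_replicates):
        ctrl = synthetic.generate_timelapse(
            [synthetic.CarrierSpec(n_carriers=n_carriers, speed=control_speed)],
            n_frames=n_frames,
            seed=seed * 1000 + rep,
        )
        depl = synthetic.generate_timelapse(
            [synthetic.CarrierSpec(n_carriers=n_carriers, speed=effect * control_speed)],
            n_frames=n_frames,
            seed=seed * 1000 + 500 + rep,
        )
        s_c = kinematics.analyze_timelapse(ctrl.channels["carrier"], ctrl.calibration)
        s_d = kinematics.analyze_timelapse(depl.channels["carrier"], depl.calibration)
        ratios.append(s_d["mean_speed_um_s"].mean() / s_c["mean_speed_um_s"].mean())
    return float(np.mean(ratios))


#: an idealised Rho-style screen: fragmentation arms raise fragment
#: number while dispersing it (lower κ); compaction arms do the reverse
FRAGMENTATION_SCREEN_ARMS = {
    "NEG": (12, 4.0),
    "RAC2": (30, 0.5),
    "RHOBTB1": (28, 0.8),
    "RHOA": (25, 1.0),
    "RHOC": (22, 1.5),
    "RHOV": (18, 2.0),
    "RND3": (6, 8.0),
    "RHOG": (7, 10.0),
}


def fragmentation_screen(
    n_cells: int = 100, seed: int = 0
) -> "tuple[float, 'np.ndarray', 'np.ndarray']":
    """Simulate the 8-arm fragmentation screen and correlate readouts.

    Returns ``(pearson_r, normalized_counts, normalized_pds)`` across
    arms. Because fragmentation arms both raise the fragment count and
    disperse the fragments, the two normalised readouts should be
    negatively correlated.
    """
    from .stats import pearson_correlation

    arms = {
        name: synthetic.GolgiDispersionSpec(n_fragments=n, angular_concentration=k)
        for name, (n, k) in FRAGMENTATION_SCREEN_ARMS.items()
    }
    screen = synthetic.simulate_screen_truth(arms, n_cells_per_arm=n_cells, seed=seed)
    pairs = [pair for cells in screen.values() for pair in cells]
    table = polar.score_cells(pairs)
    # simulate_screen_truth reuses cell ids across arms; group by treatment
    summary = polar.treatment_summary(table, control="NEG")
    counts = table.groupby("treatment")["n_fragments"].mean()
    norm_counts = (counts / counts["NEG"]).reindex(summary["treatment"]).to_numpy()
    norm_pds = summary["normalized_pds"].to_numpy()
    r = pearson_correlation(norm_counts, norm_pds).r
    return float(r), norm_counts, norm_pds
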