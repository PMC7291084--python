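"""Track moving membrane carriers and classify them by length.

Renders a 30-frame video with point-like carriers at 0.5 µm/s plus one
slow 2.5 µm tubule, then runs preprocessing, detection, greedy
nearest-neighbour linking, the >2 µm displacement filter and the
2 µm tubular/vesicular classification.
"""

import golgiscreen as gs

video = gs.generate_timelapse(
    [
        gs.CarrierSpec(n_carriers=3, speed=0.5),               # vesicular, motile
        gs.CarrierSpec(n_carriers=1, speed=0.15, length=2.5),  # tubular, slower
    ],
    n_frames=30,
    seed=4,
)
table = gs.analyze_timelapse(
    video.channels["carrier"], video.calibration, min_displacement_um=2.0
)
print(table.round(3).to_string(index=False))
print(
    f"\nmean speed {table['mean_speed_um_s'].mean():.3f} µm/s over "
    f"{len(table)} tracks with net displacement > 2 µm; "
    f"{(table['class'] == 'tubular').sum()} tubular carrier(s) (length ≥ 2 µm)"
)
# Programmed speeds (0.5 and 0.15 µm/s) are recovered per track; the
# 2.5 µm capsule is classified tubular, the point carriers vesicular.
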