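"""Shot onset and signed directional error from ball-track coordinates.

A synthetic overhead-camera track is generated with a known error angle;
the analysis detects when the cue ball leaves its 40 x 40 mm bounding box
and measures the target ball's departure angle at peak speed relative to
the pocket direction.
"""

from betarebound.synth import generate_ball_track
from betarebound.tracking import TableGeometry, detect_onset, directional_error

import numpy as np

geometry = TableGeometry()
rng = np.random.default_rng(2)

print("programmed(deg)  onset(s)  recovered(deg)")
for err in (-8.0, -2.5, 0.0, 3.0, 10.0):
    track = generate_ball_track(err, onset_time=1.0, geometry=geometry, rng=rng)
    onset = detect_onset(track, geometry)
    rec = directional_error(track, geometry)
    print(f"{err:>14.1f}  {onset:8.3f}  {rec:13.2f}")
# recovered errors match the programmed angles to ~0.1 deg; onset lags the
# programmed 1.0 s motion start by the time the ball needs to travel 20 mm.
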