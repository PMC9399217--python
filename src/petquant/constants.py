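"""Physical constants used across the package."""

import numpy as np

#: Physical half-life of carbon-11, minutes.
C11_HALF_LIFE_MIN: float = 20.364

#: Decay constant of carbon-11, 1/min.
C11_LAMBDA_PER_MIN: float = float(np.log(2.0) / C11_HALF_LIFE_MIN)

#: Default fractional blood volume used in tissue compartment fits.
DEFAULT_VB: float = 0.05

#: Strict-mode VOI diameters (mm) per VOI class.
STRICT_VOI_DIAMETERS_MM = {
    "affected-joint": 50.0,
    "contralateral-joint": 50.0,
    "blood-pool": 20.0,
    "background": 10.0,
}

#: Whole-body dosimetry frame mid-times (min post-injection).
WHOLE_BODY_FRAME_TIMES_MIN = (3.0, 10.5, 21.0, 41.0, 61.0, 81.0)

#: Dynamic quantification grid (min post-injection): nine dynamic frames
#: plus the late whole-body point at ~45 min.
DYNAMIC_FRAME_TIMES_MIN = (1.5, 3.0, 5.0, 7.0, 11.0, 14.0, 17.0, 20.0, 25.0)
LATE_FRAME_TIME_MIN = 45.0
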