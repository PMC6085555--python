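"""AOI label alphabet shared across the pipeline.

Labels are plain strings so they serialize naturally to CSV and compare
cheaply in vectorized numpy code.
"""

LEFT_EYE = "left_eye"
RIGHT_EYE = "right_eye"
NOSE = "nose"
MOUTH = "mouth"
NON = "non"
MISSING = "missing"

#: The four facial AOIs, in the default tie-break order.
FACIAL_AOIS: tuple[str, ...] = (LEFT_EYE, RIGHT_EYE, NOSE, MOUTH)

#: Every label a gaze sample can carry.
ALL_LABELS: tuple[str, ...] = FACIAL_AOIS + (NON, MISSING)

#: Combined label aggregating both eye AOIs.
EYES = "eyes"

# Dyadic gaze states.
TWO_WAY = "two_way"
ONE_WAY = "one_way"
NO_EYE_GAZE = "no_eye_gaze"
UNDEFINED = "undefined"

PAIRED_STATES: tuple[str, ...] = (TWO_WAY, ONE_WAY, NO_EYE_GAZE, UNDEFINED)
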