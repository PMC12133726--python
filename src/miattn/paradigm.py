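"""Trial timeline and band conventions for the key-press / motor-imagery task.

Each trial follows a fixed 9 s timeline, with t = 0 at the onset of the
"Select" cue (the arrow appears and the subject presses a key):

====================  ==============  =======================================
phase                 window (s)      screen / subject state
====================  ==============  =======================================
Ready                 [-2, -1)        "Ready" shown, subject resting
Start                 [-1,  0)        "Start" shown; this second is the
                                      spectral baseline
Select                [ 0,  1)        arrow shown, key pressed
Motor imagery (MI)    [ 1,  5)        guided video, right-leg imagery
Rest                  [ 5,  7)        "Rest" shown
====================  ==============  =======================================

A trial is labeled ``Attention`` when the pressed key matches the arrow and
``Inattention`` otherwise.
"""

from __future__ import annotations

# Phase windows in seconds relative to the Select cue.
READY = (-2.0, -1.0)
START = (-1.0, 0.0)
SELECT = (0.0, 1.0)
MI = (1.0, 5.0)
REST = (5.0, 7.0)

#: Full trial span relative to the cue; epochs default to this window.
TRIAL_SPAN = (-2.0, 7.0)
TRIAL_DURATION = TRIAL_SPAN[1] - TRIAL_SPAN[0]

#: Baseline used for spectral referencing (the "Start" second).
BASELINE = START

ATTENTION = "Attention"
INATTENTION = "Inattention"
CONDITIONS = (ATTENTION, INATTENTION)

# Band conventions (Hz). Alpha follows the study definition; theta/beta
# bounds are the usual EEG conventions. All are overridable per call.
THETA_BAND = (4.0, 8.0)
ALPHA_BAND = (8.0, 13.0)
BETA_BAND = (13.0, 30.0)
ANALYSIS_BAND = (1.0, 30.0)

#: 32-channel montage (10/20 plus 10/10 intermediates), as on a 32-channel
#: clinical amplifier.  Includes the channels the analysis keys on:
#: Cz (vertex, sensorimotor), F4/FC4 (right-frontal alerting network),
#: Fp1/Fp2 (frontopolar, blink-sensitive).
CHANNELS_32 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T7", "C3", "Cz", "C4", "T8",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO8", "O1", "Oz", "O2",
)

ARROWS = ("up", "down")
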