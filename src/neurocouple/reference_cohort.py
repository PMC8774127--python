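"""Published demographics of the roller-derby study cohort.

Per-subject age (years) and mean framewise displacement (mm) for the 19
female roller-derby athletes and 14 non-collision-sport controls, as printed
in the study's demographics table. These are the only subject-level values
the study reports; they serve as inputs for the in-sample statistics
(group age summaries, head-motion group comparison) and for simulations
that reuse the exact observed age/motion distributions.
"""

from __future__ import annotations

from .io_formats import SubjectRecord

ATHLETE_AGES = (
    23, 24, 24, 26, 26, 27, 28, 29, 30, 31, 32, 32, 35, 35, 36, 40, 41, 41, 45,
)

ATHLETE_MEAN_FD = (
    0.191, 0.059, 0.054, 0.146, 0.118, 0.159, 0.061, 0.062, 0.476, 0.066,
    0.095, 0.062, 0.073, 0.072, 0.163, 0.137, 0.076, 0.077, 0.064,
)

CONTROL_AGES = (19, 20, 21, 21, 21, 22, 22, 22, 23, 25, 25, 26, 29, 49)

CONTROL_MEAN_FD = (
    0.069, 0.054, 0.065, 0.062, 0.055, 0.045, 0.109, 0.066, 0.070, 0.062,
    0.138, 0.047, 0.065, 0.069,
)


def reference_subjects() -> list:
    """The 33 published subjects as :class:`SubjectRecord` objects.

    Controls first, then athletes, each in the table's ascending-age order.
    """
    subjects = [
        SubjectRecord(f"ctl{i + 1:02d}", float(a), "control", fd)
        for i, (a, fd) in enumerate(zip(CONTROL_AGES, CONTROL_MEAN_FD))
    ]
    subjects += [
        SubjectRecord(f"ath{i + 1:02d}", float(a), "athlete", fd)
        for i, (a, fd) in enumerate(zip(ATHLETE_AGES, ATHLETE_MEAN_FD))
    ]
    return subjects
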