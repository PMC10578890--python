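"""Categorical state alphabets for the bedside pupillary exam.

Pupil size (PS) is recorded as isochoric (the normal finding) or one of four
abnormalities: left/right anisochoria, bilateral miosis, bilateral mydriasis.
Photo-reactivity (PR) is recorded as bilaterally present (normal), bilaterally
absent, or unilaterally present on the right or left (three abnormal levels).
"""

from __future__ import annotations

from enum import Enum


class PupilSizeState(str, Enum):
    """Bedside pupil-size category; ISOCHORIC is the single normal state."""

    ISOCHORIC = "ISOCHORIC"
    ANISO_LEFT = "ANISO_LEFT"
    ANISO_RIGHT = "ANISO_RIGHT"
    MIOSIS_BILATERAL = "MIOSIS_BILATERAL"
    MYDRIASIS_BILATERAL = "MYDRIASIS_BILATERAL"


class PhotoReactivityState(str, Enum):
    """Pupillary light-reflex category; BILATERAL_PRESENT is the normal state."""

    BILATERAL_PRESENT = "BILATERAL_PRESENT"
    BILATERAL_ABSENT = "BILATERAL_ABSENT"
    UNILATERAL_RIGHT = "UNILATERAL_RIGHT"
    UNILATERAL_LEFT = "UNILATERAL_LEFT"


#: Canonical state orderings used for transition-matrix rows/columns.
PS_STATES: tuple[PupilSizeState, ...] = tuple(PupilSizeState)
PR_STATES: tuple[PhotoReactivityState, ...] = tuple(PhotoReactivityState)

PS_NORMAL = PupilSizeState.ISOCHORIC
PR_NORMAL = PhotoReactivityState.BILATERAL_PRESENT
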