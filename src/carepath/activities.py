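"""The closed activity vocabulary of the acute-stroke care pathway.

Fourteen activity types cover the three care settings a suspected-stroke
patient moves through: the emergency room (ER), the acute hospital, and
the long-stay (recovery) hospital.  The canonical rank encodes the
expected clinical order of the pathway — admission before imaging before
treatment before discharge — and is used both as the tie-break for
simultaneous timestamps and as the reference order when checking
timestamp consistency.
"""

from __future__ import annotations

import enum


class Setting(str, enum.Enum):
    """Care setting in which an episode takes place."""

    ER = "ER"
    ACUTE_HOSPITAL = "acute_hospital"
    LONGSTAY_HOSPITAL = "longstay_hospital"


class Activity(str, enum.Enum):
    """One of the fourteen caregiving activities of the stroke pathway."""

    ER_ADMISSION = "ER Admission"
    ER_FIRST_ATTENTION = "ER First Attention"
    ER_CT = "ER CT"
    ER_FIBRINOLYSIS = "ER Fibrinolysis"
    ER_THROMBECTOMY = "ER Thrombectomy"
    ER_OBSERVATION_ROOM = "ER Observation Room"
    ER_DISCHARGE = "ER Discharge"
    ER_EXIT = "ER Exit"
    HOSPITAL_ADMISSION = "Hospital Admission"
    HOSPITAL_FIBRINOLYSIS = "Hospital Fibrinolysis"
    HOSPITAL_THROMBECTOMY = "Hospital Thrombectomy"
    HOSPITAL_DISCHARGE = "Hospital Discharge"
    LONGSTAY_ADMISSION = "Long-stay Hospital Admission"
    LONGSTAY_DISCHARGE = "Long-stay Hospital Discharge"

    @property
    def rank(self) -> int:
        """Canonical 1-based position in the expected pathway order."""
        return _RANK[self]

    @property
    def setting(self) -> Setting:
        return _SETTING[self]


#: Activities in canonical pathway order (rank 1..14).
ACTIVITIES: tuple[Activity, ...] = tuple(Activity)

_RANK = {a: i + 1 for i, a in enumerate(ACTIVITIES)}

_SETTING = {
    Activity.ER_ADMISSION: Setting.ER,
    Activity.ER_FIRST_ATTENTION: Setting.ER,
    Activity.ER_CT: Setting.ER,
    Activity.ER_FIBRINOLYSIS: Setting.ER,
    Activity.ER_THROMBECTOMY: Setting.ER,
    Activity.ER_OBSERVATION_ROOM: Setting.ER,
    Activity.ER_DISCHARGE: Setting.ER,
    Activity.ER_EXIT: Setting.ER,
    Activity.HOSPITAL_ADMISSION: Setting.ACUTE_HOSPITAL,
    Activity.HOSPITAL_FIBRINOLYSIS: Setting.ACUTE_HOSPITAL,
    Activity.HOSPITAL_THROMBECTOMY: Setting.ACUTE_HOSPITAL,
    Activity.HOSPITAL_DISCHARGE: Setting.ACUTE_HOSPITAL,
    Activity.LONGSTAY_ADMISSION: Setting.LONGSTAY_HOSPITAL,
    Activity.LONGSTAY_DISCHARGE: Setting.LONGSTAY_HOSPITAL,
}

#: Administrative admission / discharge activity for each setting.  These are
#: derived from episode timestamps by the event-log builder rather than from
#: explicit event rows.
ADMISSION_ACTIVITY = {
    Setting.ER: Activity.ER_ADMISSION,
    Setting.ACUTE_HOSPITAL: Activity.HOSPITAL_ADMISSION,
    Setting.LONGSTAY_HOSPITAL: Activity.LONGSTAY_ADMISSION,
}

DISCHARGE_ACTIVITY = {
    Setting.ER: Activity.ER_DISCHARGE,
    Setting.ACUTE_HOSPITAL: Activity.HOSPITAL_DISCHARGE,
    Setting.LONGSTAY_HOSPITAL: Activity.LONGSTAY_DISCHARGE,
}

#: Virtual source/sink node names used by the process map and precedence
#: matrix.  They are bookkeeping nodes, never part of the activity vocabulary.
START = "START"
END = "END"
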