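"""Shared fixtures: patterns and record builders used across the suite."""
from __future__ import annotations

from datetime import date

import numpy as np
import pytest

from vfgrade.patterns import PatternId, get_pattern
from vfgrade.records import Eye, VFRecord


@pytest.fixture(scope="session")
def p24():
    return get_pattern(PatternId.HFA24_2)


@pytest.fixture(scope="session")
def p30():
    return get_pattern(PatternId.HFA30_2)


@pytest.fixture(scope="session")
def g1():
    return get_pattern(PatternId.G1)


@pytest.fixture
def make_record():
    """Builder for ad-hoc records: make_record(pattern_id, deviations, ...)."""

    def _make(pattern_id=PatternId.HFA24_2, deviations=None, eye=Eye.R,
              fp=0.05, fn=0.05, fl=0.1, right_eye_format=None, **kw):
        pattern = get_pattern(pattern_id)
        if deviations is None:
            deviations = np.zeros(pattern.n_points)
        if right_eye_format is None:
            right_eye_format = eye is Eye.R
        return VFRecord(
            patient_id=kw.get("patient_id", "T001"), eye=eye,
            exam_date=kw.get("exam_date", date(2021, 6, 1)),
            pattern_id=PatternId(pattern_id), deviations=np.asarray(deviations,
                                                                    dtype=float),
            fp_rate=fp, fn_rate=fn, fl_rate=fl,
            right_eye_format=right_eye_format)

    return _make
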