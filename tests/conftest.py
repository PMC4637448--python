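"""Shared fixtures.

The scroll-wave scenario runs are expensive (tens to hundreds of seconds of
wall time each), so every simulation that more than one test consumes is a
session-scoped fixture: the homogeneous-sheet reference reentry, the wedge /
ridge / pectinate-muscle drift runs, and the paced single-cell beats.
"""
from __future__ import annotations

import numpy as np
import pytest

from atriadrift.cell_model import RemodelParams, pace_to_steady
from atriadrift.initiation import record_cycle
from atriadrift.scenarios import af_study_params, preset, run_scenario


@pytest.fixture(scope="session")
def study_params() -> RemodelParams:
    return af_study_params()


@pytest.fixture(scope="session")
def control_params() -> RemodelParams:
    return RemodelParams.control()


@pytest.fixture(scope="session")
def control_beat(control_params):
    """Control CRN cell paced to steady state at 1 Hz."""
    return pace_to_steady(control_params, bcl=1000.0, n_beats=20)


@pytest.fixture(scope="session")
def remodelled_beat(study_params):
    """Remodelled cell paced to steady state at bcl 300 ms."""
    return pace_to_steady(study_params, bcl=300.0, n_beats=20)


@pytest.fixture(scope="session")
def library(study_params):
    """Cycle library recorded mid-strand during steady pacing."""
    return record_cycle(study_params)


@pytest.fixture(scope="session")
def sheet_run():
    """Reference 4 s reentry on the homogeneous 25x25 mm sheet."""
    return run_scenario(preset("sheet2d"))


@pytest.fixture(scope="session")
def wedge_run():
    return run_scenario(preset("wedge"))


@pytest.fixture(scope="session")
def ridge_left_run():
    return run_scenario(preset("ridge"))


@pytest.fixture(scope="session")
def ridge_right_run():
    return run_scenario(preset("ridge", site="right", duration=800.0))


@pytest.fixture(scope="session")
def ridge_left_cw_run():
    return run_scenario(preset("ridge", chirality="cw", duration=800.0))


@pytest.fixture(scope="session")
def pm1_run():
    return run_scenario(preset("pm1"))


@pytest.fixture(scope="session")
def pm3_run():
    return run_scenario(preset("pm3"))
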