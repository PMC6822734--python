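"""Shared fixtures: the four scenario runs used across the suite.

The calibrated healthy runs and the volume-matched DCM reruns are the
expensive objects here (tens of seconds each), so they are built once per
session and shared by the index, directional and acceptance tests.
"""

from __future__ import annotations

import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")

from heartloop import (
    calibrate_total_volume,
    compute_indices,
    default_initial_state,
    get_preset,
    run_to_steady_state,
)


@pytest.fixture(scope="session")
def adult_healthy_run():
    pre = get_preset("adult-healthy")
    total, result = calibrate_total_volume(
        pre.params, pre.target_lv_edv, pre.calibration_bracket)
    return {"total": total, "result": result, "indices": compute_indices(result)}


@pytest.fixture(scope="session")
def adult_dcm_run(adult_healthy_run):
    pre = get_preset("adult-dcm")
    init = default_initial_state(pre.params, adult_healthy_run["total"])
    result = run_to_steady_state(pre.params, init)
    return {"total": adult_healthy_run["total"], "result": result,
            "indices": compute_indices(result)}


@pytest.fixture(scope="session")
def child_healthy_run():
    pre = get_preset("child-healthy")
    total, result = calibrate_total_volume(
        pre.params, pre.target_lv_edv, pre.calibration_bracket)
    return {"total": total, "result": result, "indices": compute_indices(result)}


@pytest.fixture(scope="session")
def child_dcm_run(child_healthy_run):
    pre = get_preset("child-dcm")
    init = default_initial_state(pre.params, child_healthy_run["total"])
    result = run_to_steady_state(pre.params, init)
    return {"total": child_healthy_run["total"], "result": result,
            "indices": compute_indices(result)}
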