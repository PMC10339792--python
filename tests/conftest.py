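"""Shared fixtures: the published fiber parameter set and helpers."""

import warnings

import numpy as np
import pytest

from fibersas import (
    ContrastSet,
    NanofiberGeometry,
    NanofiberModel,
)

# the published simultaneous-fit parameter set for the K3W(QL)6K2 fiber
TABLE1 = {
    "a_core": 9.8,
    "a_shell": 8.4,
    "b_core": 44.1,
    "b_shell": 8.5,
    "c": 340.0,
    "d_core": 0.95,
    "d_shell": 1.36,
    "d_pep": 1.25,
    "rho_core_x": 9.07e10,
    "rho_shell_x": 1.23e11,
    "rho_solv_x": 9.37e10,
    "rho_core_n": -3.77e8,
    "rho_shell_n": 4.06e10,
    "rho_solv_n": 6.35e10,
    "n_agg": 180.0,
    "m_core": 473.0,
    "m_shell": 1866.0,
    "m_pep": 2339.0,
    "phi": 0.008,
}

SEQUENCE = "KKKW" + "QL" * 6 + "KK"
HBOND_BLOCK = "KW" + "QL" * 6


@pytest.fixture(scope="session")
def table1_geometry() -> NanofiberGeometry:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # c < 10 x cross-section is the real regime
        return NanofiberGeometry(
            a_core=TABLE1["a_core"],
            a_shell=TABLE1["a_shell"],
            b_core=TABLE1["b_core"],
            b_shell=TABLE1["b_shell"],
            c=TABLE1["c"],
        )


@pytest.fixture(scope="session")
def xray_contrasts() -> ContrastSet:
    return ContrastSet(
        rho_core=TABLE1["rho_core_x"],
        rho_shell=TABLE1["rho_shell_x"],
        rho_peg=0.0,
        rho_solv=TABLE1["rho_solv_x"],
        radiation="xray",
    )


@pytest.fixture(scope="session")
def neutron_contrasts() -> ContrastSet:
    return ContrastSet(
        rho_core=TABLE1["rho_core_n"],
        rho_shell=TABLE1["rho_shell_n"],
        rho_peg=0.0,
        rho_solv=TABLE1["rho_solv_n"],
        radiation="neutron",
    )


@pytest.fixture(scope="session")
def table1_model(table1_geometry, xray_contrasts) -> NanofiberModel:
    return NanofiberModel(
        geometry=table1_geometry,
        contrasts=xray_contrasts,
        n_agg=TABLE1["n_agg"],
        phi=TABLE1["phi"],
        background=0.0,
    )


@pytest.fixture(autouse=True)
def _silence_decoupling_warning():
    """The published geometry sits below the strict decoupling bound by
    design; the advisory warning is exercised explicitly in one test."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*decoupling.*")
        yield


@pytest.fixture()
def q_grid() -> np.ndarray:
    return np.logspace(np.log10(0.004), np.log10(0.7), 120)
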