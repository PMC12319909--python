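import numpy as np
import pytest

from csflow import Protocol


@pytest.fixture(scope="session")
def protocol() -> Protocol:
    """The CSF imaging protocol: TR 0.504 s, TE 30 ms, 45 deg, W 2.5 mm,
    21 slices, MB 3, T1 4 s, T2 1.5 s."""
    return Protocol()


@pytest.fixture(scope="session")
def recursion_oracle():
    """Independent longitudinal-recursion oracle.

    Iterates Mz <- Mz*cos(theta)*exp(-dt/T1) + M_eq*(1 - exp(-dt/T1)) from
    equilibrium over the inter-pulse intervals, then emits
    Mz*sin(theta)*exp(-TE/T2). Written as a plain scalar loop, independent of
    the closed-form implementation it checks.
    """

    def oracle(deltas, protocol: Protocol) -> float:
        mz = protocol.m_eq
        for d in deltas:
            e = np.exp(-d / protocol.t1)
            mz = mz * np.cos(protocol.flip_angle) * e + protocol.m_eq * (1.0 - e)
        return float(
            mz * np.sin(protocol.flip_angle) * np.exp(-protocol.te / protocol.t2)
        )

    return oracle
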