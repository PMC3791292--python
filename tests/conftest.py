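import numpy as np
import pytest

from pdmri import ShellMeanDecay, group_shells, mbi_btable, synthesize_signal

#: published patient-group decay parameters for the whole corpus callosum
TABLE_CC_PATIENT = (1.0, 0.55, 1.8e-3, 7.1e-5)


@pytest.fixture(scope="session")
def protocol_btable():
    return mbi_btable()


@pytest.fixture(scope="session")
def protocol_shells(protocol_btable):
    return group_shells(protocol_btable)


@pytest.fixture(scope="session")
def patient_decay(protocol_shells):
    """Noiseless shell-mean decay at the corpus-callosum patient parameters."""
    sig = synthesize_signal(TABLE_CC_PATIENT, protocol_shells)
    return ShellMeanDecay(
        b=protocol_shells.b_values,
        mean_signal=sig,
        n_volumes=np.array([s.n_volumes for s in protocol_shells]),
    )


def make_decay(shells, params):
    """Noiseless ShellMeanDecay from (S0, Mu, Du, Dr) on a shell table."""
    return ShellMeanDecay(
        b=shells.b_values,
        mean_signal=synthesize_signal(params, shells),
        n_volumes=np.array([s.n_volumes for s in shells]),
    )
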