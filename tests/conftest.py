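import pytest

import gbmflux as gf


@pytest.fixture(scope="session")
def toy_net():
    return gf.toy_brain_network()


@pytest.fixture(scope="session")
def toy_constraints():
    return gf.toy_gbm_constraints()


@pytest.fixture(scope="session")
def constrained_net(toy_net, toy_constraints):
    return gf.apply_constraint_set(toy_net, toy_constraints, "flux")


@pytest.fixture(scope="session")
def warburg_matrices(toy_net):
    mats, truth = gf.synth_expression(toy_net, gf.warburg_sim_params(seed=7))
    return mats


@pytest.fixture()
def toy_lin():
    return gf.toy_linear()


@pytest.fixture()
def toy_branch_net():
    return gf.toy_branch()
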