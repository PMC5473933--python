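import numpy as np
import pandas as pd
import pytest

from enoseml import AcquisitionSchedule, FeatureMatrix
from enoseml.synth import ChannelModel, N_COMPONENTS, SampleSpec


@pytest.fixture
def schedule():
    return AcquisitionSchedule()


def make_channel(
    name="test",
    ethanol_sensitivity=0.5,
    tau_ads=1.0,
    tau_des=2.0,
    noise_sd=0.0,
    drift_rate=0.0,
    instability_factor=1.0,
    extra_sensitivity=None,
):
    """A channel responding (by default) to ethanol only, noise-free."""
    sens = np.zeros(N_COMPONENTS)
    sens[0] = ethanol_sensitivity
    if extra_sensitivity is not None:
        sens = np.asarray(extra_sensitivity, dtype=float)
    return ChannelModel(
        name=name,
        sensitivity=sens,
        tau_ads=np.full(N_COMPONENTS, tau_ads),
        tau_des=np.full(N_COMPONENTS, tau_des),
        noise_sd=noise_sd,
        drift_rate=drift_rate,
        instability_factor=instability_factor,
    )


def make_sample(name="s", alcohol=20.0, water=0.0, flavors=0.0, known=True):
    conc = np.zeros(N_COMPONENTS)
    conc[0] = alcohol
    conc[1] = water
    conc[2:] = flavors
    return SampleSpec(
        name=name, alcohol_content=alcohol,
        component_concentrations=conc, known=known,
    )


def make_feature_matrix(X, A, sample_names=None, known=None, t_a=None,
                        columns=None):
    """Small FeatureMatrix straight from arrays (for regression/CV tests)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if columns is None:
        columns = [f"ch:p{j % 4 + 1}" if d <= 4 else f"c{j // 4}:p{j % 4 + 1}"
                   for j in range(d)]
    if sample_names is None:
        sample_names = [f"s{i}" for i in range(n)]
    if known is None:
        known = np.ones(n, dtype=bool)
    if t_a is None:
        t_a = np.full(n, 60.0)
    return FeatureMatrix(
        X=pd.DataFrame(X, columns=columns),
        A=np.asarray(A, dtype=float),
        sample_names=np.asarray(sample_names, dtype=object),
        t_a=np.asarray(t_a, dtype=float),
        known=np.asarray(known, dtype=bool),
    )
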