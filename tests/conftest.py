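import numpy as np
import pytest

from muerd import (
    PipelineConfig,
    SubjectScenario,
    generate_subject,
    make_default_layout,
    run_subject,
)


@pytest.fixture(scope="session")
def layout():
    return make_default_layout()


@pytest.fixture(scope="session")
def clean_subject(layout):
    """A strong-effect, artifact-free subject: mu at 7 Hz, BL1-preferring."""
    scn = SubjectScenario(
        subject_id="S1",
        mu_center_freq=7,
        mu_amp_bl1=6.0,
        mu_amp_bl2=4.0,
        suppression_ao=0.6,
        suppression_ae=0.5,
        n_trials=15,
        seed=42,
    )
    rec, ann = generate_subject(scn, layout)
    return scn, rec, ann


@pytest.fixture(scope="session")
def clean_analysis(clean_subject, layout):
    scn, rec, ann = clean_subject
    return scn, run_subject(rec, ann, layout, PipelineConfig(), subject_id=scn.subject_id)


def simple_recording(data, layout, sfreq=250.0):
    """Wrap an array as a Recording using the first rows of the layout."""
    from muerd import Recording

    n = data.shape[0]
    return Recording(
        data=np.asarray(data, float),
        sfreq=sfreq,
        channel_names=list(layout.channel_names[:n]),
        positions=layout.positions[:n].copy(),
    )
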