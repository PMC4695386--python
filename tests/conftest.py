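import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")

import replayvta as rv
from replayvta.decoding import fit_encoding
from replayvta.io import compute_speed


@pytest.fixture(scope="session")
def linear_session():
    """A small linear-track session with hippocampal and VTA activity."""
    cfg = rv.SimConfig(seed=11, n_trials=30)
    beh = rv.simulate_behavior(cfg)
    spikes, lfp, truth = rv.simulate_hippocampus(beh, cfg)
    vta, vta_lfp, truth = rv.simulate_vta(beh, truth, cfg)
    return {"cfg": cfg, "beh": beh, "spikes": spikes, "lfp": lfp,
            "vta": vta, "vta_lfp": vta_lfp, "truth": truth}


@pytest.fixture(scope="session")
def encoding_model(linear_session):
    s = linear_session
    speed = compute_speed(s["beh"])
    filt = s["spikes"].amplitude_filter()
    model = fit_encoding(filt, s["beh"].t, s["beh"].lin_pos,
                         s["beh"].direction, speed > 10, s["beh"].track)
    return model, filt, speed


@pytest.fixture(scope="session")
def decoded_candidates(linear_session, encoding_model):
    """Candidate events decoded in 25 ms bins, with the session bin pool."""
    from replayvta.decoding import decode
    from replayvta.replay import CandidateEvent

    s = linear_session
    model, filt, _ = encoding_model
    beh = s["beh"]
    cands = []
    for k, ev in s["truth"].events.iterrows():
        nb = int((ev.end - ev.start) / 0.025)
        if nb < 3:
            continue
        edges = ev.start + np.arange(nb + 1) * 0.025
        post = decode(model, filt, edges, with_direction=True)
        pos = float(np.interp((ev.start + ev.end) / 2, beh.t, beh.lin_pos))
        cands.append((CandidateEvent(k, (ev.start, ev.end), post, pos),
                      bool(ev.is_replay)))
    pool = np.vstack([c.posterior.P for c, _ in cands])
    return cands, pool
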