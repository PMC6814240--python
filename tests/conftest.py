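import numpy as np
import pandas as pd
import pytest

from segnoise import synthetic as syn


@pytest.fixture()
def clean_events():
    """20,000 contaminant-free events, Fano 5% at mean log10 signal 2."""
    spec = syn.FlowPopulationSpec(n_events=20_000, mu_log=2.0, fano_pct=5.0,
                                  seed=101)
    return syn.simulate_flow_events(spec)


@pytest.fixture()
def contaminated_events():
    """20,000 events with 5% debris and 5% doublets planted."""
    spec = syn.FlowPopulationSpec(n_events=20_000, mu_log=2.0, fano_pct=5.0,
                                  debris_frac=0.05, doublet_frac=0.05,
                                  seed=202)
    return syn.simulate_flow_events(spec)


def make_cross(seed, n_segregants=360, n_markers=1001, causal_idx=500,
               effect=3.0, residual_sd=1.0):
    """A synthetic cross with one nonsynonymous causal noise locus."""
    markers = syn.spike_background_mutations(n_markers, seed=seed + 7_000_000)
    markers.loc[causal_idx, "effect"] = "nonsynonymous"
    spec = syn.CrossSpec(n_segregants=n_segregants, n_markers=n_markers,
                         causal_markers=(causal_idx,),
                         causal_effects=(effect,),
                         residual_sd=residual_sd,
                         marker_positions=markers, seed=seed)
    return syn.simulate_cross(spec)
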