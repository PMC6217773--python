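"""Shared builders for simulation-backed tests."""

from ordtreat import build_design, compact_model_spec, compact_params, simulate_dataset
from ordtreat.simulate import scenario_params


def make_compact_design(n, rho=-0.5, delta=1.0, seed=0):
    ds, tp = simulate_dataset(n, compact_params(rho=rho, delta=delta), seed=seed)
    return build_design(ds, compact_model_spec()), tp


def make_weakiv_design(n, seed=0):
    ds, _ = simulate_dataset(n, scenario_params("weakiv"), seed=seed)
    return build_design(ds)
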