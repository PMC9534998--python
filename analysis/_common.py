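"""Shared configuration for the numbered analysis scripts.

Every script re-runs the (fully seeded, deterministic) pipeline and then
presents one stage of it, so the scripts stay thin and can be run in any
order.  Outputs land under results/analysis/.
"""

from pathlib import Path

from benthoval.pipeline import RunConfig, run_pipeline

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"
CONFIG = RunConfig(seed=1)

_cache = {}


def result():
    if "res" not in _cache:
        _cache["res"] = run_pipeline(CONFIG)
    RESULTS.mkdir(parents=True, exist_ok=True)
    return _cache["res"]
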