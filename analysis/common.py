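"""Shared study conditions for the numbered analysis drivers.

One cohort of 200 farms followed for 3 years, bulk-sampled monthly; every
driver reuses the same root seed so the whole analysis is reproducible
end to end.
"""

from pathlib import Path

STUDY_SEED = 7
N_FARMS = 200
N_YEARS = 3

RESULTS = Path(__file__).resolve().parent.parent / "results"
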