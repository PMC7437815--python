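#!/usr/bin/env python
"""Slow-gamma power during SWRs, per hippocampal region.

Regenerates the session from 02 (same seed), computes multitaper
spectrograms per site, z-scores each frequency bin against the session's
immobility windows, and averages 30-50 Hz power in the 0-100 ms post-onset
window over events and over sites within CA1-sr, CA3, and DG.
Outputs: results/session_features.csv
"""

from pathlib import Path

import pandas as pd

from ripplescreen.evaluation import DETECTION_FIXTURE
from ripplescreen.pipeline import process_session
from ripplescreen.synthetic import LFPSimParams, simulate_lfp_session

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main():
    RESULTS.mkdir(exist_ok=True)
    session, truth = simulate_lfp_session(LFPSimParams(seed=SEED, **DETECTION_FIXTURE))
    result = process_session(session)
    row = dict(mouse_id=result.mouse_id, session=result.session_index,
               swr_abundance_hz=result.abundance_hz,
               **{f"sg_z_{r.value.lower()}": z for r, z in result.sg_by_region.items()})
    pd.DataFrame([row]).to_csv(RESULTS / "session_features.csv", index=False)
    print(f"{len(result.events)} SWRs; planted SG amplitude "
          f"{truth.sg_mod_amp:.1f} band-SD units")
    for region, z in result.sg_by_region.items():
        print(f"  SG z during SWRs, {region.value}: {z:+.3f}")


if __name__ == "__main__":
    main()
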