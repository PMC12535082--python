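"""Score item-level questionnaire responses into canonical scale scores.

Builds a tiny batch of raw responses for the Zung anxiety scale and the
16-type self-harm inventory, then scores them.  The anxiety standard score
is the raw 20-item sum (after reverse-scoring five items) times 1.25,
rounded half-up; NSSI severity is the sum over the 16 self-harm types of
frequency code (0-3) times severity code (0-4).
"""

import numpy as np
import pandas as pd

from idpn.instruments import sas_spec, score_instrument, score_nssi_table

rng = np.random.default_rng(0)

# three respondents x 20 anxiety items, codes 1..4
sas_items = pd.DataFrame(
    rng.integers(1, 5, size=(3, 20)),
    columns=[f"item_{i}" for i in range(1, 21)],
)
sas_items.insert(0, "respondent_id", ["R1", "R2", "R3"])
print(score_instrument(sas_items, sas_spec()))
# SAS column: the standard anxiety score, higher = more severe symptoms

# self-harm inventory: R1 reports nothing, R2 one moderate type twice
nssi = pd.DataFrame(0, index=range(2), columns=(
    [f"freq_{i}" for i in range(1, 17)] + [f"sev_{i}" for i in range(1, 17)]
))
nssi.insert(0, "respondent_id", ["R1", "R2"])
nssi.loc[1, "freq_3"], nssi.loc[1, "sev_3"] = 2, 3
print(score_nssi_table(nssi))
# nssi_severity 0 vs 6 (= 2 x 3); nssi_flag marks who reported any self-injury
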