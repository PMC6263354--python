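"""Compare knockdown mechanisms calibrated to the same steady-state fold.

CRISPRi blocks transcription (existing protein decays at the dilution
rate); a tagged protease removes the protein pool directly.  Both are
calibrated to 5-fold repression here: the protease acts faster, and
stacking it on CRISPRi keeps the speed while multiplying the fold.
"""

import numpy as np

from fermlogic.knockdown import (
    ExpressionParams,
    KnockdownConfig,
    crispri_block_for_fold,
    protease_decay_for_fold,
    simulate_knockdown,
    steady_state_fold,
)

p = ExpressionParams()
scenarios = {
    "CRISPRi 5x": KnockdownConfig(crispri_block=crispri_block_for_fold(5)),
    "protease 5x": KnockdownConfig(
        protease_extra_decay=protease_decay_for_fold(5, p)
    ),
}
scenarios["both"] = KnockdownConfig(
    crispri_block=scenarios["CRISPRi 5x"].crispri_block,
    protease_extra_decay=scenarios["protease 5x"].protease_extra_decay,
)

for name, k in scenarios.items():
    tc = simulate_knockdown(p, k, horizon=14.0)
    below = np.nonzero(tc.values <= 0.5)[0]
    t50 = tc.times[below[0]] - k.induction_time if len(below) else float("nan")
    print(
        f"{name:12s} steady fold {steady_state_fold(p, k):5.1f}   "
        f"time to 50% after induction: {t50:.2f} h"
    )
print("\nIn this linear model folds multiply across mechanisms (5x5=25),")
print("and protein removal outpaces transcript run-out whenever the added")
print("protease decay exceeds the mRNA turnover rate.")
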