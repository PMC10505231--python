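"""The two label-generating rules: NGS arm-mean fold change and FISH
signal ratio.

A tumor is oligodendroglioma by NGS when the mean linear fold change of
both the 1p and 19q arms falls strictly below 0.8; by FISH, an arm is
deleted when more than half of the evaluable nuclei (> 60 required) show
a single target signal.
"""

import pandas as pd

from milfc import FISHCount, fish_codeletion, fish_deletion_call, mean_arm_fc, ngs_classify

genes = pd.DataFrame(
    {
        "gene": ["TP73", "MEGF6", "CDKN2C", "CRX", "ZNF44", "MAN2B1"],
        "arm": ["1p", "1p", "1p", "19q", "19q", "19q"],
        "log2_fc": [-0.9, -0.7, -0.8, -0.85, -0.75, -0.9],
    }
)
m1p = mean_arm_fc(genes, "1p")
m19q = mean_arm_fc(genes, "19q")
call = ngs_classify(m1p, m19q)
print(f"NGS: mean FC 1p = {m1p:.3f}, 19q = {m19q:.3f} -> {call.tumor_type.value}"
      f"{' (borderline)' if call.borderline else ''}")

c1p = fish_deletion_call(FISHCount("1p", n_evaluated=85, n_single_target=52))
c19q = fish_deletion_call(FISHCount("19q", n_evaluated=92, n_single_target=60))
print(f"FISH: 1p {c1p} (52/85), 19q {c19q} (60/92) -> {fish_codeletion(c1p, c19q)}")
print("both assays agree: this profile is a 1p/19q-codeleted oligodendroglioma")
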