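"""Relative qPCR quantification (2^-ddCt) and the RANKL/OPG ratio.

Ct values are normalized to the 18S reference gene per sample, then to
the mean of the healthy (calibrator) condition, and exponentiated.
The RANKL/OPG ratio summarizes net osteoclastogenic signaling: values
above 1 indicate a shift toward bone resorption.
"""

import pandas as pd

import perionet as pn

rows = []
# synthetic Ct values: disease samples amplify RANKL ~2 cycles earlier
for i, (cond, rankl, opg) in enumerate([
        ("healthy", 24.1, 23.0), ("healthy", 24.4, 23.2),
        ("healthy", 23.9, 22.9), ("healthy", 24.2, 23.1),
        ("periodontitis", 22.0, 22.8), ("periodontitis", 21.7, 23.0),
        ("periodontitis", 22.3, 22.6), ("periodontitis", 21.9, 22.9)]):
    sample = f"{cond[0]}{i % 4 + 1}"
    rows += [(sample, cond, "Tnfsf11", rankl),
             (sample, cond, "Tnfrsf11b", opg),
             (sample, cond, "Rn18s", 9.0)]
qpcr = pd.DataFrame(rows, columns=["sample", "condition", "gene", "ct"])

rq_rankl = pn.delta_delta_ct(qpcr, target="Tnfsf11", reference="Rn18s",
                             calibrator="healthy")
rq_opg = pn.delta_delta_ct(qpcr, target="Tnfrsf11b", reference="Rn18s",
                           calibrator="healthy")
ratio = pn.rankl_opg_ratio(rq_rankl["rq"], rq_opg["rq"])

out = pd.DataFrame({"condition": rq_rankl["condition"],
                    "rq_rankl": rq_rankl["rq"],
                    "rq_opg": rq_opg["rq"],
                    "rankl_opg_ratio": ratio})
print(out.round(3).to_string())
print("\nmean ratio per condition (> 1 favors bone resorption):")
print(out.groupby("condition")["rankl_opg_ratio"].mean().round(3)
      .to_string())
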