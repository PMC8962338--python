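"""The Box-Jenkins condition-deviation transform on the worked micro set.

Eight molecules assayed under two conditions are labeled by the nM cutoff
table, then each raw descriptor is re-expressed as
D = (GTI - avg_actives(element)) / (std * ps(element)).  A positive D
means the molecule's descriptor sits above the average of the actives
assayed in the same context; actives of each context average to D = 0 by
construction.
"""

from ptml import (
    CutoffTable,
    annotate_activity,
    fit_box_jenkins,
    generate_worked_micro_dataset,
    gti_table,
    transform,
)
from ptml.synthetic_fixtures import MICRO_FEATURES, MICRO_SPECS

records = annotate_activity(generate_worked_micro_dataset(), CutoffTable.default())
gti = gti_table(list(records["smiles"]), specs=MICRO_SPECS)
stats = fit_box_jenkins(records, gti)

print("a-priori active probabilities ps(element):")
for kind in ("ma", "tg", "ei"):
    for element in stats.avg[kind]:
        print(f"  {kind}={element!r}: ps = {stats.ps(kind, element):.2f}")

features = transform(records, gti, stats, MICRO_FEATURES)
out = records[["compound_id", "smiles", "tg", "value", "label"]].join(features)
print("\ndeviation features:")
print(out.to_string(index=False, float_format=lambda v: f"{v:8.4f}"))

actives = records["label"] == 1
print(
    "\nmean D over all training actives (zero by construction within each"
    f" element):\n{features[actives].mean().round(12).to_string()}"
)
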