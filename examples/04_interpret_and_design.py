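"""Interpretation of a trained model: which deviation features matter
(sensitivity values) and in which direction to push them (propensities).

SV > 1 means clamping that feature to its training mean degrades the
classifier, i.e. the feature carries signal; a propensity of "Increase"
means actives average higher than inactives on that feature, so designs
should raise it.
"""

import warnings
from pathlib import Path
from tempfile import TemporaryDirectory

warnings.filterwarnings("ignore")

from ptml import (
    RunConfig,
    SyntheticConfig,
    class_propensities,
    design_guidelines,
    run_pipeline,
    sensitivity_values,
)
from ptml.synthetic_fixtures import write_dataset

with TemporaryDirectory() as tmp:
    csv = Path(tmp) / "synth.csv"
    write_dataset(SyntheticConfig(seed=1), csv)
    result = run_pipeline(
        RunConfig(input_csv=str(csv), out_dir=str(Path(tmp) / "out"), model=2),
        write=False,
    )

train = result.records[result.records["split"] == "train"]
x = result.features.loc[train.index, result.selected]

prop = class_propensities(x, train["label"])
sv = sensitivity_values(result.mlp, x, train["label"])
table = prop.join(sv[["sv", "rank"]]).sort_values("rank")
print(table.to_string(float_format=lambda v: f"{v:9.4f}"))

print("\ndesign guidelines (most sensitive first):")
for line in design_guidelines(prop, sv)[:5]:
    print(" -", line)
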