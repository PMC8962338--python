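"""Multi-condition screening and drug-likeness profiling of candidates.

Each candidate's raw descriptors are deviated against every experimental
condition the model was trained under and scored; the TSAD column counts
how many features sit inside their training ranges (in-domain only when
all do).  The summary is the fraction of conditions predicted active --
the multi-target profile a versatile inhibitor should maximize.
"""

import warnings
from pathlib import Path
from tempfile import TemporaryDirectory

warnings.filterwarnings("ignore")

from ptml import (
    ExperimentalCondition,
    RunConfig,
    SyntheticConfig,
    drug_likeness,
    model_features_of,
    parse_smiles,
    run_pipeline,
    screen,
)
from ptml.synthetic_fixtures import write_dataset

with TemporaryDirectory() as tmp:
    csv = Path(tmp) / "synth.csv"
    write_dataset(SyntheticConfig(seed=1), csv)
    result = run_pipeline(
        RunConfig(input_csv=str(csv), out_dir=str(Path(tmp) / "out"), model=2),
        write=False,
    )

CANDIDATES = {
    "heteroaryl-urea": "O=C(Nc1ccc(F)cc1)NCc1ncccn1",
    "plain-alkane": "CCCCCCCCCC",
}
conditions = [
    ExperimentalCondition(r["ma"], r["tg"], r["ei"])
    for _, r in result.records[["ma", "tg", "ei"]].drop_duplicates().iterrows()
]
mols = [(name, parse_smiles(smi)) for name, smi in CANDIDATES.items()]
screened = screen(
    mols, result.mlp, result.stats, model_features_of(result.mlp), conditions
)
print(screened.to_string(index=False, float_format=lambda v: f"{v:6.3f}"))
print("\nfraction of conditions predicted active:")
for name, frac in screened.attrs["summary"].items():
    print(f"  {name}: {frac:.0%}")

print("\ndrug-likeness profiles:")
for name, smi in CANDIDATES.items():
    profile = drug_likeness(parse_smiles(smi))
    d = profile.to_dict()
    print(
        f"  {name}: MW {d['MW']:.1f}  MlogP {d['MlogP']:.2f}  AlogP {d['AlogP']:.2f}  "
        f"PSA {d['PSA']:.1f}  RBN {d['RBN']}  "
        f"Lipinski {d['lipinski']}  Ghose {d['ghose']}  Veber {d['veber']}"
    )
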