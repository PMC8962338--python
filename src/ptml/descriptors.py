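"""Raw-descriptor (GTI) tables for collections of molecules.

Descriptors depend only on the chemical structure, so they are computed
once per unique canonical SMILES and shared across all the bioactivity
cases of that chemical.
"""

from __future__ import annotations

import pandas as pd

from . import quad_descriptors, topo_descriptors
from .chemgraph import MolecularGraph, parse_smiles
from .specs import DescriptorSpec, model_specs


def gti_block(graph: MolecularGraph, specs: list[str]) -> dict[str, float]:
    """Evaluate a mixed list of descriptor specs on one molecule."""
    out: dict[str, float] = {}
    for spec_str in specs:
        spec = DescriptorSpec.parse(spec_str)
        if spec.family == "ASq":
            out[str(spec)] = quad_descriptors.descriptor_value(graph, spec)
        else:
            out[str(spec)] = topo_descriptors.descriptor_value(graph, spec)
    return out


def gti_table(
    smiles: list[str], model: int | None = None, specs: list[str] | None = None
) -> pd.DataFrame:
    """GTI matrix indexed by canonical SMILES (one row per unique chemical).

    Pass either ``model`` (1 or 2, using the published descriptor blocks)
    or an explicit ``specs`` list.
    """
    if specs is None:
        if model is None:
            raise ValueError("provide a model number or an explicit spec list")
        specs = [s for s, _ in model_specs(model)]
    rows: dict[str, dict[str, float]] = {}
    for smi in smiles:
        graph = parse_smiles(smi)
        canonical = graph.canonical_smiles()
        if canonical not in rows:
            rows[canonical] = gti_block(graph, specs)
        if smi not in rows:  # allow lookup under the supplied form as well
            rows[smi] = rows[canonical]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=specs)
    df.index.name = "smiles"
    return df
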