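# Methods

This note records the model, the numerical conventions, and the design
choices made where the underlying method descriptions leave the design
open. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`.

## Data model

A bioactivity *case* is a chemical assayed under an experimental condition
`cj = (ma, tg, ei)`: the activity measure (a protein IC50 `IC50(nM)p` or a
cell-viability IC50 `IC50(nM)c`), the target (protein or cell line) and
the assay annotation. Curation drops rows missing SMILES, value or units,
rejects non-positive values, canonicalizes SMILES, and keeps the lowest
value among duplicates sharing (canonical SMILES, condition), first seen
winning exact ties. Labels are dichotomous: `IA = 1` when the value is at
or below the condition's nM cutoff (boundary inclusive), else `−1`. The
bundled roster covers 44 conditions — three proteins with cutoffs 1100 nM
(caspase-1), 1635 nM (TNF-alpha) and 50 nM (IGF1R) across five assay
annotations, and 31 pancreatic-cancer cell lines at 6449.735 nM. Only nM
units are accepted; there is no silent unit conversion.

## Descriptor engines

**Molecular graphs.** Hydrogen-suppressed heavy-atom graphs parsed by
RDKit with aromatic perception; implicit hydrogen counts are retained per
atom. `nB` counts bonds without multiplicity (a double bond is one bond)
and is the size normalizer (`NTI = TI / nB`). Molecules with fewer than
two heavy atoms are rejected package-wide since the normalization divides
by the bond count; dot-disconnected inputs keep the largest component by
default (configurable to reject).

**Atomic properties.** `Hyd` and `Mol` are the published Wildman–Crippen
per-atom logP and molar-refractivity contributions, `Psa` the Ertl
TPSA per-atom contributions, and `Gas` the Gasteiger–Marsili iterative
partial-charge equalization (12 damped iterations by default; hydrogen
charges folded into their heavy atom, so neutral molecules sum to 0
within 1e-3) — all evaluated through RDKit, which implements exactly
these published schemes. `Ato`/`Aw` (standard atomic weights), `E`
(Pauling electronegativity), `Pol` (dipole polarizability, 1e-24 cm³)
and the covalent radii and valence-electron counts behind `Ku` ship as a
versioned CSV (`data/element_properties.csv`). Kupchik's vertex degree is
`(r_C / r_X) · (Zv − h)` with `r` the single-bond covalent radius. The
exact atom-typing dialect of legacy descriptor software is not published;
small numeric offsets against those programs are expected and accepted —
the oracle tests pin the mathematics, not bit-compatibility.

**Spectral moments.** The bond adjacency matrix is indexed by bonds:
off-diagonal 1 when two bonds share an atom (the line-graph adjacency),
diagonal `w(i,j) = p_i/δ_i + p_j/δ_j` (atomic property over heavy-atom
degree, summed over the bond's endpoints), the established convention of
the spectral-moment descriptor family. `SM(PP)k` is the trace of the k-th
matrix power (k = 0 returns `nB`), computed by repeated multiplication in
double precision — exact to machine precision for the k ≤ 15 used here.
Gasteiger weighting uses signed charges; absolute values are not taken.

**Connectivity indices.** `X(s)o` sums over connected subgraphs with `o`
bonds the product over subgraph atoms of `δ^(−1/2)`, with `δ` the degree
in the whole molecule. Valence degrees are `Zv − h` for second-row atoms
and `(Zv − h)/(Z − Zv − 1)` beyond. Subgraphs are enumerated exactly
(ESU enumeration on the line graph, capped at order 8; the published
blocks need ≤ 7) and classified by the Kier–Hall scheme: chains (Ch)
contain a cycle; acyclic subgraphs are paths (P, no degree-3 vertex),
clusters (C, branched with no degree-2 vertex) or path-clusters (PC,
mixed). `e(s)o` evaluates the same construction on the line graph with
line-graph degrees. Brute-force oracles (closed-walk counting, exhaustive
edge-subset filtering) verify both engines to 1e-9 on the test battery.

**Stochastic quadratic indices.** `S` is the heavy-atom adjacency with
each row divided by its degree; `ASq_m(x)_T = Σ_{i∈T} x_i [S^m x]_i`. The
order `m` is realized as the m-th matrix power (length-m walks), the
formalism of the quadratic-index family, although some method prose
reads "topological distance"; the walk reading is the documented choice
here. The local form is the non-symmetrized row restriction, and group
aggregation is plain summation. An empty group yields 0.

## Box–Jenkins transform

`D(GTI)_e = (GTI − avg(GTI)_e) / (std(GTI) · ps(e))`, applied separately
to each element kind (ma, tg, ei), giving feature names `D(<spec>)<kind>`.
Three conventions were genuinely open and are fixed as follows:

- `avg(GTI)_e` averages over the **training actives** of element value
  `e` (the active count is what the a-priori probability is built from);
  this is the single biggest interpretive decision.
- `std(GTI)` is the **sample** (n−1) standard deviation over **all**
  training cases, not per element — the notation is unsubscripted.
- `N_T(e)` in `ps(e) = n(e)/N_T(e)` is the training total **within the
  same element value**, so `ps` is the active fraction of that context.

Consequences used as invariants: the deviation features of a kind average
to exactly 0 over the training actives of every element value (and hence
over all training actives), and `ps ∈ (0, 1]` for every retained element.
Unseen element values at transform time raise — no silent imputation.
A useful corollary: on training data the active class mean of every
deviation feature is ~0, so the propensity direction is carried by the
sign of the inactive mean.

## Feature selection and classifiers

Candidates are the full grid of (raw spec × element kind): 45 for the
Model-1 block, 42 for Model-2. Ranking uses entropy criteria on 24
equal-width bins over the pooled range with Laplace α = 1: the primary
score is the mutual information between the binned feature and the class
label (the differential-Shannon-entropy form `H(X) + H(Y) − H(X,Y)`), the
Jeffreys divergence `Σ(p−q)ln(p/q)` between the class-conditional
histograms breaks ties. The exact formula behind the legacy ranking tool
is not published; this reconstruction is config-exposed (bins, α).
Constant features score 0. Selection is greedy by rank under the
`|PCC| < 0.7` redundancy bound, with the mandatory constraint of at least
one feature per element kind (a swap step enforces it; unsatisfiable
constraints raise listing the missing kinds). Target sizes default to 15
(Model 1) and 14 (Model 2).

The MLP has one logistic hidden layer (default width 45), trained
full-batch by LBFGS (≤ 500 iterations) with a fixed seed via
scikit-learn, plus an L2 weight-decay penalty (`alpha`, default 1.0):
with a 45-unit hidden layer and a few hundred training cases an
unpenalized fit memorizes label noise, and weight decay is the standard
remedy; the exact internals of the original closed-source trainer are
unspecified, so determinism and honest generalization took priority. The
LDA baseline is the closed-form scikit-learn discriminant on the same
features. Fitted weights are extracted into a JSON-serializable bundle
that performs its own forward pass (verified against scikit-learn's
`predict_proba` to 1e-9), so serialized models are self-contained.

Metrics: `Sn = 100·CCC_a/N_a`, `Sp = 100·CCC_i/N_i`,
`Ac = 100·(CCC_a+CCC_i)/(N_a+N_i)`, and the Matthews correlation
coefficient with the safe convention MCC = 0 when the denominator
vanishes. Local Sn/Sp are computed per element value of each kind and
reported as NaN when a class is absent in the subset. The identity
`Ac = (Sn·N_a + Sp·N_i)/(N_a+N_i)` holds for every report and is tested.

**Applicability domain.** Per-feature closed `[min, max]` training
ranges; a case's TSAD is the number of its features inside their range,
and it is in-domain iff TSAD equals the feature count. Boundary values
count as inside. Out-of-domain predictions are still reported, flagged.

## Interpretation and design support

Propensities are the sign rule on class means (Increase iff active mean
exceeds inactive mean). Sensitivity values follow the mean-substitution
convention of the original modeling environment's sensitivity analysis:
SV = (error with the feature clamped to its training mean) / (baseline
error), ranked descending; SV ≈ 1 marks an uninformative feature. With a
zero baseline error the ratio is undefined — SVs are flagged and ranking
falls back to the perturbed error. Screening deviates a candidate's raw
descriptors against every condition in the roster and scores each; a
second model can be attached as a concordance filter. Fragment assembly
into new molecules is deliberately manual: the package emits propensity/
guideline reports and screens user-supplied candidate SMILES; it does not
generate structures.

Drug-likeness: Lipinski (MW ≤ 500, MlogP ≤ 4.15 or AlogP ≤ 5 as the
config-exposed fallback, donors ≤ 5, acceptors ≤ 10), Ghose
(160 ≤ MW ≤ 480, −0.4 ≤ AlogP ≤ 5.6, 40 ≤ MR ≤ 130, 20 ≤ nAT ≤ 70) and
Veber (RBN ≤ 10, PSA ≤ 140). AlogP/MR are Wildman–Crippen, PSA is Ertl's
TPSA, RBN excludes terminal, ring and amide C–N bonds (the dominant
convention). MlogP is the 13-parameter Moriguchi regression implemented
in-package with SMARTS structural counts; the rarely-triggered correction
terms (intramolecular hydrogen bond, amphotericity, β-lactam) use
simplified SMARTS definitions, so MlogP values for molecules dominated by
those motifs carry extra uncertainty.

## Synthetic data

The generator emulates a curated multi-condition inhibition table. Its
defaults are the study conditions used throughout the tests: 160
chemicals spread over 7 conditions (3 proteins across 2 assay
annotations plus 3 cell lines, ~2.5 conditions per chemical, ≈ 400
cases), a 0.4 active fraction per condition, and an 85% concordance
between a chemical's fragment pool and its planted label. Chemicals are
assembled from a validity-checked grammar: the active-enriched pool is
built on heteroatom-rich motifs (2-aminopyrimidine, triazine, urea,
carbamate, glycinamide cores with amine/ether/morpholine/4-halophenyl
decorations), the inactive-enriched pool on alkyl chains and bare
carbocycles — so descriptors with known direction (e.g. heteroatom-group
quadratic indices) carry the signal. Activity values are drawn
multiplicatively around the condition cutoff within [0.15, 0.8] (actives)
or [1.3, 6.0] (inactives) of it, keeping every value at least 20% away
from the cutoff so annotation recovers the planted label exactly. Every
condition is guaranteed ≥ 2 actives and ≥ 2 inactives. A fixed seed fully
determines the output.

What the generator does **not** emulate: the value distributions, target
panels, chemical diversity and class imbalance of real screening
repositories, assay-to-assay systematic shifts, or activity cliffs.
Passing tests on this data therefore demonstrate the correctness and
internal consistency of the pipeline and the learnability of a planted
signal at n ≈ 400 — not real-data predictive performance, which in the
reference setting required thousands of curated cases.

The companion micro fixture (8 molecules, 2 conditions, three descriptors
chosen to be hand-tractable: `X(P)1`, `SM(Ato)1`, `Ne(P)1`) ships with a
hand-derived expected-value file (`data/micro_expected.json`) exercising
the whole transform chain to 1e-9.

## Problem sizes and determinism

The test suite and acceptance script run the synthetic pipeline at ≈ 400
cases with Model-2 descriptors (Model-1 descriptors are exercised on the
same data in dedicated tests); descriptor oracles run on molecules ≤ 8
bonds/atoms where brute force is exact. These sizes were chosen so a full
run completes in seconds while every numerical path is still covered
exactly. All randomness flows through explicit seeds (generator, split,
MLP initialization); repeated runs are byte-identical, which the CLI
tests assert on the serialized artifacts.

## Known limitations

- Descriptor values are faithful to the published mathematics but not
  bit-compatible with the legacy closed-source tools that inspired them
  (atom-typing dialects, aggregation norms and ranking formulas there are
  unpublished).
- The MI-DSE reconstruction and the Box–Jenkins active-average reading
  are documented interpretations, config-exposed where practical.
- Moriguchi MlogP correction terms are simplified (above).
- Subgraph enumeration is exact and therefore exponential in order; the
  order-8 cap keeps it tractable for drug-sized molecules but very dense
  polycycles can be slow.
- Stereochemistry, 3D geometry and conformer-dependent properties are out
  of scope.
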