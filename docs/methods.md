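# Methods

This note documents the model and numerical choices behind `celltab`: what
is simulated, which conventions fill gaps the tabular format leaves open,
and what the synthetic fixtures do and do not establish about real models.

## Model-definition files

A model is eight tab-separated files, each with one header row (headers are
ignored on read). Strict tab separation and `.` decimals; every malformed
numeric cell is reported with its row/column address, never silently
coerced.

* **OmicsData** — one row per gene: HGNC name, gene copy number, mRNA
  molecules per cell (mpc), gene inactivation rate (1/s), gene activation
  rate (1/s), constitutive and maximal transcription rates (molecules/s per
  active copy), mRNA degradation rate (1/s), protein mpc, protein half-life
  (s), translation rate constant (1/s). Protein abundance and half-life may
  be empty; an empty cell is an explicit missing value, not zero, because
  zero is a legal rate. Row order is canonical for the stochastic module.
* **Species** — name, home compartment, initial concentration (nM relative
  to the home compartment), comma-separated ENSEMBL gene identifiers.
  Transcripts are ordinary species. The tabular format gives no rule tying
  a transcript species to its OmicsData row, so the package adopts a naming
  convention: a species called `m_<GENE>` is the transcript of gene
  `<GENE>` (prefix configurable). The hybrid loop needs this mapping to
  write sampled copy numbers back into the ODE state.
* **Ratelaws** — name, home compartment, then either a single nonnegative
  number (mass-action constant; reactants and products come from the
  stoichiometric matrix) or a formula followed by one value per local
  parameter. Local parameter names start with `k`, are unique within the
  formula, and their values follow in order of first appearance.
* **StoichiometricMatrix** — species × reactions integer grid; row order
  must equal the Species file, column order the Ratelaws file (validation
  is order-sensitive by design: permuting one without the other fails).
* **GeneReg** — genes × regulator species; rows follow OmicsData order.
  `0` means no effect; `A; B` is a signed Hill coefficient (positive
  activates, negative represses) and a half-maximal concentration (nM,
  must be positive).
* **Compartments** — name, volume (liters), GO term.
* **Observables** — species × observables 0/1 membership; an observable is
  a volume-corrected protein total.
* **Initializer** (optional) — eleven columns, ragged rows: species
  override (1–2), mRNA adjustment (3–4), parameter override (5–6; 7
  reserved), excluded observable (8), single-parameter scan (9–11). The
  column roles follow the initialization workflow; the exact layout is
  this package's own dialect choice.

## Compilation

The compiler validates cross-file consistency, then builds one symbolic
rate expression per reaction. Units are nM and seconds throughout.

* **Compartment correction.** Rate laws are evaluated in the reaction's
  home compartment; a reactant whose home compartment differs contributes
  `c · V_home/V_rxn` (for a cytoplasmic receptor in an extracellular
  binding reaction this is the `V_c/V_e` factor). Species derivatives are
  scaled back: `dc_i/dt = Σ_j S_ij v_j V_rxn(j)/V_home(i)`, so every
  species stays in home-compartment nM. Mass-action reactant exponents are
  the absolute stoichiometric coefficients (a −2 squares the term).
  Formula laws are taken verbatim — any cross-compartment correction
  inside a user formula is the author's responsibility; only mass-action
  laws are corrected automatically.
* **Formula grammar.** Arithmetic (`+ − * / **`), parentheses, species
  names, local parameters; no conditionals or function calls. Every
  identifier is checked against the declared names before the expression
  is parsed (sympy), so an undeclared symbol is a hard error with the
  reaction named.
* **Parameter renaming.** Globals are assigned in ascending rate-law
  order: reaction *j* yields `k<j>` (mass-action) or `k<j>_<i>` (the
  *i*-th formula parameter). The mapping is a bijection from
  (reaction, local name) pairs and is exported as the ParamsAll report.
* **SBML export.** Level 3 Version 2 via libsbml. The kinetic-law math is
  the rate expression times the reaction-compartment size, which makes a
  standard concentration-semantics SBML interpreter reproduce the
  derivative rule above exactly. Compartments carry GO annotations,
  species their ENSEMBL identifiers; identifiers are sanitized
  deterministically (invalid characters to `_`, collision suffixes) with
  original names kept in the SBML `name` attributes, so import restores
  them. libsbml serializes doubles at 15 significant digits; round-trip
  agreement is therefore to ~1e-14 relative, and export → import → export
  is an exact fixpoint. The gene-expression bundle is not representable in
  plain SBML and returns empty on import.

## Hybrid simulation

* **Exchange interval** 30 s (configurable). Each window: integrate the
  ODEs (LSODA; default rtol 1e-6, atol 1e-9 nM), evaluate regulation at
  the post-integration protein state, update gene/mRNA state, overwrite
  transcript species with the new counts converted to nM in the
  transcript's home compartment. At t = 0 transcript species are
  synchronized to the OmicsData mRNA counts.
* **Stochastic sampling** is a tau-leap with rates frozen at the window
  start: at most one switch per gene copy per window (Bernoulli
  `1 − exp(−k dt)`), Poisson births/deaths, deaths truncated at zero.
  Exact SSA inside a 30 s window is unnecessary at per-window event rates
  well below one and would not change the window-boundary statistics
  measurably; the tau-leap keeps the cost per window constant.
* **Regulation** acts on transcription only (the GeneReg file
  parameterizes nothing else); switching rates are constant. Activators
  combine through a saturating OR-gate sum, repressors multiply;
  the rate per active copy is `(k_const + k_max·u)·w`, which reduces to
  `k_const` with no regulators and saturates at `k_const + k_max`.
* **Deterministic mode** replaces sampling by the expected-value update
  `m ← m + dt·(n f_active r − k_deg m)` with
  `f_active = k_act/(k_act+k_inact)` — exactly the mean of the tau-leap
  step, so the deterministic trajectory is the mean-field limit of the
  hybrid one on the same window grid, and its fixed point is the analytic
  stationary mean. Gene states are reported as `n·f_active`.
  Deterministic runs are seed-independent; hybrid runs are bit-reproducible
  under a fixed seed.
* **Death** ends a run when cleaved PARP strictly exceeds PARP (role
  species configurable; auto-detected as `PARP`/`cPARP` when present), at
  the end of the offending window. Unconfigured roles disable the check.
* **Negative concentrations** from stiff-integrator noise are clamped to
  zero inside `(−1e-6, 0)` nM; anything more negative aborts the run as a
  genuine model error. Recording is at every window boundary by default
  (30 s resolution); `record_stride` coarsens it.
* **Dosing**: ligand concentrations overwrite the state at t = 0;
  additional dose events fire at later window boundaries, supporting
  two-phase protocols (pre-conditioning, then treatment).

## Initialization

* **Targets**: measured proteomics (mpc → nM) where present, otherwise
  mRNA × gene-level protein/mRNA ratio (imputation is linear in mRNA).
* **Steady state** is a long unstimulated deterministic run — capped at
  1000 simulated hours — with a stationarity check every simulated hour
  (largest relative state change per hour below 1e-8 stops the run); a
  300 s exchange interval is used here since nothing stochastic happens.
* **Calibration** is iterative proportional fitting: simulate to steady
  state, measure each gene's volume-corrected total over the species
  carrying its ENSEMBL identifier (transcripts excluded), multiply its
  translation rate constant by target/current, repeat (cap 25 iterations,
  tolerance 1%). For a linear production–decay chain one update is exact
  (`k_TL = k_deg P_target / m*`); complexes converge geometrically.
  Proportional updates were chosen over gradient steps because they are
  exact on linear chains and need no step-size tuning. A zero target
  zeroes the rate directly (loss-of-function contexts). Excluded
  observables are reported but not updated. The translation parameter of
  each gene is auto-detected as the unique global parameter of the unique
  reaction containing the gene's transcript symbol; ambiguous wiring
  requires an explicit map.
* **Phenotype check**: a deterministic, unstimulated run over the horizon
  (default 48 h) must show neither death nor S-phase entry; unconfigured
  role species make a check vacuous, with a notice.
* **Parameter scan**: log-uniform grid, deterministic run per point,
  smallest passing value selected (the selection rule is this package's
  choice; the scan table is returned in full so any other rule can be
  applied).
* **Coordinate-wise fit**: parameters fitted one at a time over a
  25-point log-spaced grid spanning ±2 decades around the current value,
  keeping the best SSE against a reference trajectory of one observable
  before moving on. The grid contains the current value at its center, so
  the SSE is monotone non-increasing across steps. 25 points give a
  1/6-decade resolution; the grid range matches the fitting protocol the
  initialization workflow prescribes, the resolution is this package's
  default.

## Population layer

Sweeps are the Cartesian product of species-value and parameter-value
lists, each condition replicated `num_cells` times. Per-cell seeds derive
from a seed sequence keyed on (condition, cell), so results are identical
for any worker count and run order; volume overrides (`Vol_cyto`,
`Vol_nuclear`) replace compartment volumes before compilation. S-phase is
scored at a single evaluation time (default: end of run) as summed
Cyclin E + A + B strictly above 20 nM; an any-time-before-t variant exists
but is off by default. Dead cells are excluded from S-phase counts — a
dead cell is not in S-phase; the precedence is this package's convention.
Fractions carry the binomial s.e.m. `sqrt(pct(100−pct)/n)`. Parallelism is
a local process pool; the sweep semantics do not depend on it.

## Synthetic fixtures

`celltab.synthetic` generates complete model-definition sets whose
behavior is known in closed form: per gene a telegraph gene, its
transcript, a translated protein (formula law) with first-order decay
(mass-action); optionally a cross-compartment ligand–receptor binding step
with a Michaelis–Menten clearance law (so both compiler branches and the
volume correction are exercised), Hill-regulated genes, a PARP/cPARP death
pair with tunable cleavage, and a cyclin triple with tunable induction.
Compartments mirror a mammalian cell's four (cytoplasm ~5.3e-12 L,
nucleus ~1.8e-12 L, mitochondria ~3.7e-13 L, extracellular medium
~5e-5 L). Default rates describe a slow-switching gene: 2 copies,
symmetric switching at 5e-3/s, 0.01 mpc/s transcription per active copy,
~2 h mRNA half-life, ~19 h protein half-life — a stationary mean of
100 mRNA and ~1e4 protein copies per cell, realistic orders of magnitude
for a mammalian transcript. Initial conditions sit at the analytic steady
state so deterministic runs start flat and hybrid runs start at
stationarity.

What the toys do **not** emulate: the scale (hundreds of species,
thousands of reactions), feedback-rich signaling topologies, realistic
cell-cycle or apoptosis machinery, or measured omics inputs. Passing tests
establish that the compiler, the stochastic module, the hybrid loop, the
calibration and the population layer implement their contracts — not that
any particular biological model is correct.

## Verification strategy and problem sizes

The test suite checks the compiled RHS against an independently
hand-assembled oracle (plain loops and `eval` over the input files — no
shared code with the compiler) on randomized models; stationary moments of
the stochastic module against telegraph/birth–death closed forms using
batch-means standard errors (20 000+ windows per rate combination);
mean-field convergence of hybrid populations (200 cells per replicate,
median over three replicates, 100× copy-number contrast — the deviation of
a population mean is itself a heavily time-correlated random quantity, so
single-realization comparisons across scales are unreliable); calibration
and coordinate-fit recovery against closed forms; and SBML round-trips.
Simulation horizons in tests (0.5–2 h of simulated time, 50 h for
stationary averages) are chosen so each check resolves its effect within
seconds while keeping every statistical assertion at the 3-standard-error
level.

## Known limitations

* No cell division or lineage tracking (the cell cycle can be scored, not
  executed), no spatial structure, no cell–cell communication.
* No transcription-decay regulation (protein state modulates transcription
  only) and no chromatin states beyond the two-state telegraph.
* One switch per gene copy per window (tau-leap); at switching rates
  approaching 1/30 s⁻¹ the window would need shortening.
* No automatic model merging; combining two model-definition sets requires
  curation by the modeler.
* SBML import restores the deterministic network only; the gene-expression
  bundle lives in the tabular files.
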