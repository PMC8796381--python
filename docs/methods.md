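# Methods

## Model and assumptions

A metabolic model is the tuple (S, lb, ub, c): a sparse stoichiometric
matrix S over ordered metabolites × reactions, per-reaction flux bounds in
mmol·gDW⁻¹·h⁻¹, and a linear objective. All analyses assume steady state
(S·v = 0) and linearity; thermodynamic/loopless constraints, quadratic
objectives, parsimonious FBA and flux sampling are out of scope.
Reversibility is derived, never stored: a reaction is reversible iff its
lower bound is negative. When a file format omits bounds, the COBRA
conventions apply: (−1000, 1000) for reversible reactions, (0, 1000)
otherwise.

GPR rules are boolean trees over gene identifiers. The grammar accepted by
the parser: identifiers are maximal runs of non-whitespace characters other
than parentheses and the bare keywords `and`/`or` (case-insensitive); `and`
binds tighter than `or`; there is no negation; blank text is the
distinguished always-satisfied rule. This precedence convention follows
dominant ecosystem practice rather than any single format specification.
Knockouts close bounds to (0, 0) instead of deleting reactions, so matrix
dimensions and result-array coordinates are identical across variants.

All model edits return modified copies. This mutation-free contract is what
lets the screening framework apply variants to one base model from many
workers without coordination.

## Solver

The LP backend is HiGHS through `scipy.optimize.linprog`, behind a narrow
seam (matrix, bounds, objective in; status, objective value, primal vector
out) so it can be swapped. Defaults: primal/dual feasibility tolerance
1e−9, objective values trusted to 1e−6 relative; both configurable via
`Tolerances`. These are engineering choices matching common LP solver
defaults, not quantities derived from any data.

Degeneracy policy: alternate optima are pervasive in metabolic LPs, so only
the objective value and FVA range endpoints carry a determinism contract.
Flux vectors are returned but are *some* optimal vertex; tests and
downstream code never compare them across formulations.

## Analyses

**FVA.** The γ constraint is a linear row on the objective *expression*
(`cᵀv ≥ γ·Z*` for maximization), not a bound change on the objective
reaction — this stays correct when the objective spans several reactions.
When Z* = 0 the row degenerates to `cᵀv ≥ 0` for every γ; this is
documented, not special-cased. Default γ is 1.0 and overridable. The unit
of parallelism is one LP (one reaction, one direction) per task.

**Deletion screens** report `optimal` with objective 0 ("zero growth") as
distinct from `infeasible`; the two are never coerced into each other
because conflating them loses information. Pair knockouts have set
semantics: (g, g) equals the single deletion.

**Production envelopes** find the feasible range [lo, hi] of the modulated
reaction with two plain LPs (no objective-fraction constraint), place
`n_points` evenly spaced levels inclusive of both endpoints, and min/max
the target at each fixed level. When hi − lo < 1e−9 the grid collapses to a
single level.

## Screening framework

A variant is an ordered tuple of plain-value transformation descriptors
(knockout, bound change, objective change) plus a label; it carries no live
references, so it pickles across process boundaries. Analyses cross the
worker boundary by registered name plus keyword arguments, never by
closure — required for process pools and for replayable logs. Grids are
Cartesian products of variant axes in user-given order; cells are assembled
in row-major order (last axis fastest) regardless of completion order,
which is what makes results identical for any worker count. The transport
is a single-machine `ProcessPoolExecutor`; multi-node distribution is out
of scope — the portable content is the task decomposition itself. No
in-scope analysis is stochastic, but an optional integer seed is threaded
per cell (offset by the flat cell index) for analyses that declare a
`seed` parameter. `screen` aborts on the first failing cell; 
`screen_fallible` stores a structured error value per failing cell so long
screens survive sporadic solver failures, and logs a summary.

## Community joining

Members keep their internal networks untouched; ids are prefixed
`memberId#` (with `#` forbidden in member ids, making collisions
impossible in practice and detected anyway). For each shared metabolite X,
an environment metabolite `X_env` is created; each member's exchange for X
(detected structurally: exactly one participating metabolite — the `EX_`
prefix is only a convention and loses when the two criteria disagree)
becomes a transfer whose environment-side coefficient is the negated
member-side coefficient scaled by the member's normalized abundance.
`EX_X_env` ({X_env: −1}) connects the environment to the outside with the
spec'd bounds (negative flux = uptake into the environment). Shared
metabolites are matched across members by bare id after stripping `_e` /
`[e]` suffixes, overridable per member. Abundance-scaling of transfer
stoichiometry is one of several conventions in the literature; it is the
one implemented, stated here because the choice changes the numbers.
Member objective coefficients are carried over scaled by abundance, so FBA
on the joined model directly maximizes the abundance-weighted community
objective; `community_objective` builds explicit growth-reaction objectives
when members use unweighted biomass reactions.

## Formats

COBRA JSON (schema v1) is the canonical read/write dialect; unknown
document keys are preserved in the model's annotations and re-emitted, and
writes are byte-deterministic with full binary64 precision. SBML is read
only, L3 with fbc v2 only: bounds come from the fbc bound parameters (the
`reversible` attribute is ignored with a warning when it disagrees), and
boundary-condition species are excluded from the constraint set. The COBRA
Toolbox MAT struct reader covers the core field set (S, lb, ub, rxns, mets,
genes, grRules, c, plus rxnNames/metNames); compartments are recovered from
conventional id suffixes since the dialect stores none. The fixtures module
includes minimal SBML and MAT *writers* used only to materialize
cross-format twins for testing the readers.

## Synthetic fixtures: what they emulate and what they do not

The fixtures are small networks with closed-form answers: a linear chain
(optimum = uptake bound; fully determined fluxes at γ = 1), a branched
network (high-yield product branch, optionally gene-gated or isozyme-gated,
versus an ungated wasteful branch at yield\_w — knockout of the product
branch leaves `uptake · yield_w`; with yield\_w = 0 one unit of waste
displaces exactly one unit of product, giving the linear 10/5/0 envelope at
uptake 10), a diamond (two equivalent routes; the canonical degenerate
optimum), and a random union of capacity-limited pathway motifs sharing one
substrate (optimum = min(uptake bound, total capacity)). Defaults — uptake
10, yields 1.0/0.5, bounds (0, 1000) — are conventional toy-model values.
Randomness flows only through one seeded NumPy generator; the seed is
recorded in the model's annotations and the same seed reproduces the model
byte-identically.

These fixtures exercise the solver path, GPR gating, degenerate optima,
parallel decomposition and format round-trips honestly, but they are tiny,
loop-free and mass-consistent by construction. Passing tests therefore
demonstrates correctness of the algorithms and contracts, not performance
or numerical behavior on genome-scale reconstructions with thousands of
reactions, thermodynamically infeasible loops, or inconsistent annotations.

Problem sizes used in the automated checks — 200 random models for FBA
oracle agreement, 50 plus the named fixtures × four γ values for FVA, a
16-cell screen for determinism, a 101-reaction model for the parallel FVA
check — were chosen as the smallest sizes that exercise every code path
(multiple pathways, gated and isozyme-gated entries, binding and
non-binding capacities) while keeping the default suite fast.

## Known limitations

- One LP backend (HiGHS via SciPy); the seam is narrow but no alternative
  backend ships.
- SBML write support is absent by design; conversion always lands on JSON.
- Community joining implements one abundance convention; dynamic community
  simulation and abundance fitting are out of scope.
- The worker pool is single-machine; no cluster scheduler integration,
  checkpointing, or multi-node transport.
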