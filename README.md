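# fluxscreen

Constraint-based analysis of genome-scale metabolic models with a composable,
parallel variant-screening framework.

## The problem

Constraint-based reconstruction and analysis (COBRA) treats an organism's
metabolism as a constrained linear system: a stoichiometric matrix **S**
(metabolites × reactions), flux bounds **lb ≤ v ≤ ub**, and a linear
objective **c**. At steady state,

```
maximize  cᵀ v
s.t.      S v = 0
          lb ≤ v ≤ ub
```

is *flux balance analysis* (FBA). *Flux variability analysis* (FVA) asks, for
each reaction, how far its flux can move while retaining a fraction γ of the
optimum Z\*: minimize and maximize `v_j` subject additionally to
`cᵀv ≥ γ·Z*`. Gene-deletion screens close the bounds of every reaction whose
boolean gene–protein–reaction (GPR) rule evaluates false and re-solve.
Production envelopes sweep one reaction across its feasible range and record
the extreme achievable fluxes of a target reaction at each level.

All of these decompose into many *independent* linear programs. fluxscreen
makes that decomposition a first-class object: a **variant** is a
serializable model transformation (knockout, bound change, objective
change), a **screen** runs any registered analysis over the Cartesian grid
of variant axes on a worker pool, and the outputs are collected into a dense
multi-dimensional array whose coordinates are the grid coordinates. Results
are deterministic for any worker count and any scheduling, so a screen with
8 workers is byte-for-byte the screen with 1 worker, only faster. Community
(multi-organism) models are built by joining member models through a shared
environment compartment.

Who it's for: systems-biology researchers who need FBA/FVA/deletion/envelope
analyses over many model variants — knockout libraries, media sweeps,
community compositions — without hand-writing parallel code.

## Worked example

A small branched network: substrate uptake capped at 10, a high-yield
product branch (1 product per substrate) gated by the isozyme rule
`gP or gP2`, and an ungated wasteful branch (0.5 product per substrate).

```python
from fluxscreen import fixtures, fba, screen, Variant, Knockout

model = fixtures.make_branched(10.0, 1.0, 0.5, gene_gating=True, isozyme=True)
sol = fba(model)
print("status:", sol.status)          # status: optimal
print("objective:", sol.objective_value)  # objective: 10.0

axes = [[Variant((), label="wild-type"),
         Variant((Knockout({"gP"}),), label="ko gP"),
         Variant((Knockout({"gP", "gP2"}),), label="ko gP+gP2")]]
result = screen(model, axes, "fba_objective", workers=2)
for label, value in zip(result.labels, result.values):
    print(f"{label}: {value}")
```

prints

```
wild-type: 10.0
ko gP: 10.0
ko gP+gP2: 5.0
```

Reading: the wild type routes all 10 units of substrate through the
high-yield branch (objective 10). Knocking out `gP` alone changes nothing —
the isozyme `gP2` keeps the branch open. Knocking out both forces everything
through the wasteful branch at half yield (objective 5): a synthetic-lethal
pattern. The same grid can run FVA per variant (`analysis="fva"`), which is
the flux-variability-in-knockouts workflow, and `screen_fallible` keeps
going when individual cells fail, storing explicit error values instead.

The same analyses are available from the shell:

```sh
fluxscreen fixture branched -o branched.json
fluxscreen fba branched.json            # objective + flux table, exit 0
fluxscreen fva branched.json --gamma 1.0 --workers 4
fluxscreen deletions branched.json --pairs gP:gP2
fluxscreen envelope branched.json --target EX_P_e --modulated EX_W_e --points 3
fluxscreen screen branched.json --axis ko:gP,gP2,gU --analysis fba_objective
```

Exit codes: 0 success, 1 usage/validation error, 2 infeasible/unbounded,
3 solver environment failure.

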