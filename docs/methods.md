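# Methods

## Problem and scope

`covloc` solves the maximal covering location problem (MCLP): choose at most
P facility sites to maximise the total demand lying within a travel-time
threshold T of at least one chosen site. Coverage is binary — a demand node
is either fully covered (some open site within T) or not at all — and
demand is aggregated to points (postcode-sector centroids with annual visit
counts). The package deliberately excludes related objectives (p-median,
p-centre, set covering), capacity constraints, geocoding and travel-time
computation from road or transit networks: travel matrices are inputs.

## Coverage construction

`a_ij = 1` iff `t_ij <= T`, with an **inclusive** boundary: "within T
minutes" is read as ≤ T. Times must be finite and non-negative; no symmetry
or metric property is assumed, so asymmetric public-transport matrices are
fine.

## Solvers

**Greedy.** Repeatedly open the candidate with the largest *uncovered*
demand gain; never remove a site. Stops at the budget P or as soon as no
candidate adds positive gain — the latter matters when the candidate pool
cannot cover all demand (e.g. restricted to existing clinics), where a
"repeat until no unmet demand remains" rule would not terminate. Ties break
to the lowest candidate id so runs are deterministic. Because weighted
coverage is monotone submodular, greedy attains ≥ (1 − 1/e) ≈ 63.2 % of the
optimum at every budget, its marginal gains are non-increasing, and its
solutions are nested in P — one unbounded run yields the whole trade-off
curve.

**Exact.** The 0/1 integer program is solved with the HiGHS branch-and-bound
backend behind `scipy.optimize.milp`. Among coverage-optimal solutions the
facility count is not unique (redundant sites can ride along), yet the
planning output of interest *is* the facility count; a second MILP therefore
minimises the number of open sites subject to attaining the stage-1
coverage. A per-site penalty in a single solve was considered instead, but
with real-valued (projected) demands no fixed penalty is provably smaller
than every possible objective gap, so the two-stage lexicographic solve is
used; the stage-2 coverage floor carries a 1e-9 relative slack to absorb
MILP round-off, far below any demand weight.

**Enumeration.** Brute force over all subsets of size ≤ P, refusing more
than 10⁶ subsets. Canonical tie-break: scan sizes ascending and keep only
strict improvements, so the reported optimum has minimum cardinality and is
lexicographically smallest within that cardinality. This is an independent
oracle — it shares no code path with the MILP route — and the two are
cross-checked on hundreds of random instances in the tests.

**Metaheuristics.** Standard forms, all driven by one `numpy` generator
seeded from a single integer, hence bit-reproducible:

* *Simulated annealing* — binary incumbent, single-site swap/flip
  neighbourhood, geometric cooling (default factor 0.995 per step from an
  initial temperature of 2 % of total demand), Metropolis acceptance,
  20 000 evaluations.
* *Genetic algorithm* — population 100 of binary site vectors, tournament
  selection (size 3), uniform crossover (rate 0.9), bit-flip mutation at
  rate 1/|J|, random-drop repair of cardinality violations, 2 elites,
  200 generations.
* *Tabu search* — best-admissible swap neighbourhood, fixed tenure 7 on
  moved sites, aspiration when a move beats the best known objective,
  2 000 iterations.

All three are initialised from the greedy solution, so they can never return
a worse objective than greedy; the defaults above are calibration choices,
overridable per method through `solver_params` or the `[solver.*]` config
sections. Returned solutions are pruned of zero-contribution sites so
facility counts are meaningful. Move evaluation is incremental: a vector of
per-node cover counts is maintained and a swap costs two column updates
rather than a full re-evaluation.

## Scenario pipeline

A scenario fixes candidate pool (`existing_only` / `all`), mode and
threshold (defaults 30 min public transport, 15 min car — the historical
weighted-average patient travel times of the motivating study), a budget
policy (`unbounded`, `fixed:K`, `sweep:K`) and a solver list.
`min_facilities_for_coverage` increases P incrementally until the target
coverage level is reached (for greedy, by reading the nested trace; for
other solvers, re-solving per P) and raises — reporting the achievable
maximum — when the level is unreachable with the full candidate pool.
"Optimal found %" in comparison tables is operationalised as the fraction of
a stochastic solver's runs matching the best objective observed across all
solvers at the same budget, since the term has no standard definition;
stochastic solvers get per-run seeds derived deterministically from the
scenario master seed. Coverage fractions are compared unrounded internally
(with 1e-12 float guards); percentages are rounded only in reports.

## Synthetic geography

The generator emulates a shire county of the Hampshire type: `n_demand=278`
sector centroids, `n_centres=28` cluster centres carrying existing clinics,
a 60 km square region, and total demand 188 054 visits/yr. Cluster weights
are lognormal (σ = 1) so a couple of conurbation-like clusters dominate;
an `urban_fraction` (default 0.5, mirroring a county with half its
population in one conurbation) of nodes is Gaussian-scattered (σ = 2 km)
around weighted clusters and the rest is uniform rural background. Node
demand is proportional to the cluster-mixture intensity with lognormal
multiplicative noise (σ = 0.8) to reproduce heavy skew, rescaled to the
demand total exactly. Car times are straight-line distance × detour factor
1.3 at 40 km/h; public-transport times are car times × 2.2 plus 8 min of
waiting — the multiplier/wait pair is a calibration default chosen so the
facility-count gap between 30-min public-transport and 15-min car coverage
roughly matches the motivating study's pattern, not a claim about any real
network. What the generator does **not** emulate: road-network topology,
transit schedules and their asymmetries, coastline/boundary shape, and any
correlation between demand and transport access. Passing tests on synthetic
instances therefore validate the *solvers and pipelines*, not any statement
about a specific real county; county-specific headline numbers require the
real travel matrices.

**Planted optima.** For solver testing, `plant_optimum` builds geometries
with a provably unique optimum: P well-separated clusters (centres ≥ 4r
apart, where r is the car range at threshold T), each a ring of 8 equal-
demand nodes at radius 0.95r around its centre. Each centre covers its whole
ring; any sector-centroid candidate covers at most 3 ring nodes (the
90-degree chord, 1.34r, already exceeds r), and rings cannot see each other
(≥ 2.1r apart). Hence every budget-P set other than the centres strands most
of one ring and is strictly worse, making the planted centres the unique —
and unique minimum-cardinality — maximiser. Infeasible requests (clusters
that cannot fit in the region) raise instead of silently degrading.

## Numerical choices and degenerate inputs

* Demands are real-valued (projection makes them fractional); objective
  comparisons between solvers use absolute/relative guards of 1e-6–1e-9.
* P = 0 returns the empty solution; an all-zero coverage matrix yields
  objective 0 for every method; `T = 0` covers only exact-zero times.
* Greedy `argmax` on ties takes the lowest index — documented, tested, and
  relied on for reproducibility.
* Instance label matching trims whitespace and uppercases before comparing,
  since postcode formatting varies between sources; travel matrices are
  realigned to table order by label, not position.
* Demand projection multiplies each node by Σ_s share·growth with row shares
  validated to sum to 1 ± 1e-9.

## Problem sizes used in validation

The test and reproduction suites use enumeration-friendly random instances
(40 demand nodes × 10 sites, budgets 1–5, 200 instances for the oracle
cross-check), 20 planted instances with 2–5 clusters at T = 10 min, and the
full-size synthetic county (278 × 306) for the scenario pipeline — sizes at
which every check, including the MILP solves, completes in seconds while
still exercising the county-scale code paths.

## Known limitations

* The supplementary data workbook of the motivating study is not bundled;
  `import-s1` assumes canonical sheet names/columns and is the adaptation
  point once a real workbook is inspected. Headline percentages for a real
  county can only be reproduced from its actual travel matrices.
* Metaheuristic defaults are tuned for county-scale instances; much larger
  instances would need bigger budgets (and the GA's Python-level population
  loop becomes the bottleneck).
* Binary coverage is a modelling choice inherited from the MCLP: partial or
  decaying coverage near the threshold is not represented.
* No capacity modelling: a selected clinic is assumed able to absorb all
  demand assigned to it.
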