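# funcarto

Functional cartography of multilayer network communities.

Brain regions reorganize their functional interactions from one task to
the next faster than anatomy can change.  Given a stack of
per-condition connectivity matrices — for example 64 task-state (or 27
rest-window) correlation matrices over the same set of regions —
`funcarto` asks two questions of every named *system* (a predefined set
of regions such as the default-mode or fronto-parietal network): how
cohesively is it recruited as a network community across conditions,
and how consistently does it integrate with other systems?  The answers
place each system on a 3×3 grid of network roles, from *ephemeral
integrator* to *stable loner*.

The pipeline:

1. **Connectivity** — per-condition Pearson correlation of node time
   series (optionally after regressing out a task design matrix),
   Fisher-z transformed; resting recordings are windowed into
   11-sample pseudo-conditions first.
2. **Multislice community detection** — the matrices become slices of
   one multilayer network with categorical interslice coupling ω, and
   community structure is found by maximizing the multislice
   modularity

   `Q = (1/2μ) Σ_{ijsr} [(A_ijs − γ_s V_ijs) δ_sr + δ_ij ω] δ(g_is, g_jr)`

   (Newman–Girvan null `V_ijs = k_is k_js / 2m_s` within each slice)
   with an ensemble of generalized Louvain restarts.
3. **Allegiance and coefficients** — the ensemble is summarized by the
   module allegiance matrix `P_ij` (probability that nodes i, j share a
   community), from which recruitment `R_S` and integration `I_S`
   coefficients are computed per region and per system, along with node
   flexibility (fraction of slice transitions that change a node's
   community).
4. **Roles** — each coefficient is compared against a permutation null
   (node-to-system assignment shuffled, system count and sizes
   preserved); below / within / above the 95% band maps to
   {ephemeral, unstable, stable} × {loner, connector, integrator}.

Since no public dataset ships with the method, the `synthetic` module
generates planted multilayer networks, role scenarios, and
block-covariance time series with known ground truth; the test suite
validates every stage against independent oracles (exhaustive
optimization, literal summation, exact counting).

See `docs/methods.md` for the full model description, parameter
conventions, and known limitations.

## Worked example

```python
import funcarto as fc

# plant 4 systems of 8 nodes over 8 slices: 10% label flips,
# within-community weights ~N(0.8, 0.1), others ~N(0.2, 0.1)
scenario = fc.PlantedScenario.uniform(
    4, 8, 8, flip_prob=0.1, mu_in=0.8, mu_out=0.2, sigma=0.1, seed=11
)
net, truth = fc.generate_planted_multilayer(scenario)

ensemble = fc.run_ensemble(net, n_runs=25, seed=5)
print(f"best Q over {ensemble.n_runs} restarts: {ensemble.qualities.max():.4f}")

flex = fc.ensemble_flexibility(ensemble)
print(f"mean network flexibility: {flex.network_mean:.4f}")

result = fc.functional_cartography(ensemble, scenario.system_map,
                                   n_perm=1000, seed=9)
print(result.roles[["recruitment", "integration", "role"]].round(3))
```

prints

```
best Q over 25 restarts: 0.3933
mean network flexibility: 0.2218
        recruitment  integration          role
system                                        
S01           0.770        0.088  stable loner
S02           0.767        0.095  stable loner
S03           0.836        0.063  stable loner
S04           0.766        0.087  stable loner
```

Each planted system is recruited well above the permutation null
(recruitment ≈ 0.77–0.84 versus a null mean near 0.3) and integrated
well below it, so all four are classified *stable loners* — planted
coherent blocks that rarely mix.  The mean flexibility ≈ 0.22 reflects
the 10% label-flip rate plus optimizer variability.

The same pipeline is available from the shell:

```sh
funcarto simulate --systems 4 --nodes-per-system 8 --slices 8 \
    --flip-prob 0.1 --seed 11 --out sim/
funcarto detect --matrices sim/slices --gamma 1.0 --omega 0.45 \
    --runs 100 --seed 42 --out det/
funcarto cartography --ensemble det/ --systems sim/systems.tsv \
    --nperm 1000 --seed 7 --out carto/
```

Every command writes a `manifest.json` (parameters, seeds, input
checksums, version) sufficient to re-run bit-identically.  A
`gridsearch` subcommand scans (γ, ω) and selects the point maximizing
the variability of node flexibility; `pipeline` chains detection and
cartography.

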