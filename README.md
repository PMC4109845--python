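# midgeswarm

Correlation, susceptibility and interaction-range analysis for insect
swarms — and for any 3D trajectory data of groups that hover without
aligning.

## The problem

Midge swarms look like the opposite of collective behaviour: unlike bird
flocks or fish schools they have no global order.  The polarization

    Φ = | (1/N) Σ_i v_i / |v_i| |

sits at the level expected of N independent random headings (~√(8/3πN)),
and so do the rotational and dilatational order parameters.  Yet order is
a blunt probe.  The sharper one is *correlation*: after subtracting the
group's collective modes — translation V, optimal rotation R (least-squares
superposition), uniform dilatation α — each individual keeps a residual
velocity fluctuation δv_i, made dimensionless as

    φ_i = δv_i / sqrt((1/N) Σ_k |δv_k|²)        so (1/N) Σ φ_i·φ_i = 1 .

The connected correlation function and its cumulative integral

    C(r) = Σ_{i≠j} φ_i·φ_j δ(r − r_ij) / Σ_{i≠j} δ(r − r_ij)
    Q(r) = (1/N) Σ_{i≠j} φ_i·φ_j θ(r − r_ij) ,     χ = max_r Q(r)

measure how far (first zero r0 of C) and how much (susceptibility χ) the
fluctuations are shared.  Because Σφ_i = 0, Q(∞) = −1 exactly — a built-in
sanity check on every analysed frame.

The package implements the complete chain around these estimators:

* **null model** — the Non-interacting Harmonic Swarm (NHS): independent
  Langevin particles in a critically damped harmonic trap.  It *looks*
  like a swarm but has C(r) ≈ 0 and tiny χ, so whatever χ a real group
  shows above it is evidence of interaction;
* **Vicsek model in a central potential** — metric alignment within a
  radius rc plus a harmonic pull to the origin.  Scanning the confinement
  (hence density, hence x = r1/rc with r1 the nearest-neighbour distance)
  crosses an order–disorder transition where χ peaks, and the peak grows
  with system size;
* **critical scaling fit** — χ = a·(x − x_c)^(−γ) on the disordered
  branch, profiled over x_c with bootstrap confidence intervals;
* **percolation** — the linking scale λc at which a giant cluster (≥ θ of
  the group) forms scales as λc = s·r1, so a transition point x_c measured
  in body lengths converts to a metric interaction range rc/BL = x_c·s;
* **permutation statistics** — Spearman rank correlation with a two-sided
  permutation P-value, used to show χ follows r1/BL (metric interaction
  set by body size) rather than bare r1.

## Worked example

```python
from midgeswarm import NHSConfig, nhs_baseline_chi, analyze_event
from midgeswarm.fixtures import correlated_trajectory

traj = correlated_trajectory(n=150, corr_length=0.2, n_frames=20, seed=1)
summary = analyze_event(traj)
chi_nhs, _ = nhs_baseline_chi(NHSConfig(n=150, steps=12_000, transient=4_000,
                                        sample_every=250, seed=1))
print(f"r1 = {summary.r1:.4f} m, r0 = {summary.r0:.4f} m")
print(f"chi = {summary.chi:.2f} vs NHS baseline {chi_nhs:.3f}")
```

prints

```
r1 = 0.0865 m, r0 = 0.2306 m
chi = 2.64 vs NHS baseline 0.077
```

i.e. the fluctuations are correlated out to ~2.7 nearest-neighbour
distances and the susceptibility is ~34× the non-interacting baseline,
even though the same trajectory's polarization (0.05) is *below* the
uncorrelated band (0.072 ± 0.031): strong correlation without order.

## The analysis, step by step

The `analysis/` scripts run the study end to end, each printing what it
found and writing tables under `results/`:

| script | what it shows |
|---|---|
| `01_order_parameters.py` | Φ, R, Λ sit inside the uncorrelated band |
| `02_correlation_susceptibility.py` | C(r), r0 ≫ r1, χ of order one |
| `03_nhs_null.py` | the NHS baseline χ, ~30× below the correlated swarm |
| `04_vicsek_scan.py` | order–disorder scan, χ peak grows with N, critical fit |
| `05_percolation.py` | λc/r1 constant across a 500× density range |
| `06_interaction_range.py` | metric test and rc/BL estimate on events of known rc |

A thin CLI wraps the same library calls
(`midgeswarm analyze|simulate-nhs|simulate-vicsek|scan|percolation|report`,
each with `--config --seed --out --log-level`).

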