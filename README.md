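# fibrenet

Individual-based simulation of dynamically crosslinked three-dimensional
fibre networks, with quantifiers of the order that emerges from the
crosslink dynamics.

Biological fibre scaffolds — the extracellular matrix (ECM) of tissues —
acquire strikingly different architectures (aligned bundles, curved sheets,
disordered meshes) without any external guidance.  `fibrenet` implements a
minimal mechanical model of this process: `N_fib` rigid spherocylinder fibre
units of length `L_fib` and radius `R_fib` move in a periodic box under
overdamped dynamics,

```
mu_fib L_fib   dX_k/dt = Σ_m (F_rep_km + p_km F_rest_km)
mu_fib L_fib^3 dw_k/dt = Σ_m (T_rep_km + p_km (T_rest_km + T_align_km)) ∧ w_k
```

with three elementary interactions: a Hertzian contact repulsion
(`|F_rep| = α_rep (2R_fib − d)^{3/2} (2R_fib)^{-1/2}`), linear crosslink
springs of stiffness `α_rest` attached at the closest points of a pair when
the link forms (`p_km = 1`), and a nematic alignment torque at each link
derived from `V = −(α_align/2)(w_k·w_m)²`.  Links appear and disappear
through Poisson processes with frequencies `ν_link` and `ν_unlink`; the
stationary linked fraction of an eligible pair is
`χ_link = ν_link/(ν_link + ν_unlink)`.

Order is measured per snapshot by

* `Al_k` — a [0, 1] local alignment indicator of each fibre's neighbourhood
  (0 for isotropic neighbours, ≈ 0.7 for planar, 1 for unidirectional), and
  its system mean `Al_sim`;
* `N_linkperfib = N_links/N_fib` — the emergent connectivity;
* `A_max` — the semi-major axis of the covariance ellipse of the
  stereographically projected fibre directions (≈ 1 for isotropic systems,
  small for globally aligned ones);
* a three-state classification: **aligned** (`Al_sim ≥ 0.7`, `A_max ≤ 0.45`),
  **curved** (`Al_sim ≥ 0.7`, `A_max > 0.45`), **unorganized** otherwise.

## Worked example

```python
import fibrenet as fn

box = fn.DomainBox.cube(15.0)
params = fn.ModelParams(n_fib=300, nu_link=0.1, chi_link=0.5, T_final=2000.0)
traj = fn.run_simulation(params, box, seed=1, n_frames=10)
for fr in traj.frames[-3:]:
    s = fr.summary
    print(f"t={s.t:7.1f}  Al_sim={s.al_sim:.3f}  N_linkperfib={s.n_link_per_fib:.3f}"
          f"  A_max={s.a_max:.3f}  {s.state_label}")
```

prints

```
t=  718.8  Al_sim=0.923  N_linkperfib=1.150  A_max=0.618  curved
t= 1199.0  Al_sim=0.984  N_linkperfib=1.110  A_max=0.300  aligned
t= 2000.0  Al_sim=0.998  N_linkperfib=0.897  A_max=0.092  aligned
```

— a dense remodelling network (`ν_link = 0.1`) self-organizes from a random
initial state into a globally aligned architecture: the local indicator
saturates near 1 while the projection ellipse shrinks well below the 0.45
threshold.  Re-running with `nu_link=0.0` leaves the network unorganized
(`Al_sim ≈ 0.5`, `A_max ≈ 1`), the signature of a non-remodelling network
locked in its initial disorder.

The same machinery is scriptable from a shell:

```
fibrenet simulate --config run.yaml --seed 42 --out traj.h5
fibrenet sweep    --config sweep.yaml --seed 0 --out sweep_out/
fibrenet quantify traj.h5 --out summary.csv
fibrenet export   traj.h5 --format vtk --out frames/
```

Configuration files (YAML/TOML/JSON) resolve against the reference
parameter set (`L_fib=6`, `R_fib=0.5`, `α_rep=12.5`, `α_rest=5.0`,
`α_align=2.0`, `d_link_max=d_link_eq=1`, 30³ box, `T_final=5·10⁴`); any
field can be overridden, unknown keys are rejected.

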