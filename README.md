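# sirstreat

Analysis toolkit for a planar SIRS epidemic model with saturated incidence
`βSI/(1+αI²)`, constant-capacity treatment `h(I) = k·1{I>0}`, and constant
immigration of susceptible and infective individuals.

The package provides:

* **model_core** — validated parameters, the treatment function, and the
  three system variants (full 3-D `(S, I, R)`, reduced planar `(I, R)` on
  the invariant plane `S+I+R = N0 = A/d`, and the orbitally equivalent
  rescaled planar system), plus the thresholds `N0` and `R0 = k/(pA)`.
* **equilibria** — the equilibrium cubic `f(I)`, companion-matrix root
  finding, Vieta consistency checks, domain filtering against
  `D = {I>0, R>0, I+R<N0}`, and regime classification by `R0`.
* **stability** — the closed-form Jacobian at equilibria (cross-checked
  against finite differences), trace/determinant classification, and a
  grid-sampled Dulac-divergence certificate for global stability when
  `R0 < 1`.
* **hopf** — linearization entries of the rescaled system, the trace-zero
  Hopf condition with `δ`, `ω = √δ`, the closed-form Lyapunov focal number
  `σ`, and an exact-symbolic normal-form cross-check.
* **dynamics** — adaptive DOP853 integration of all variants, invariance
  checking, and unstable-cycle detection via backward-time integration with
  a Poincaré return map (unstable cycles are attracting in reversed time).
* **io_cli** — YAML/JSON configuration, fixture generators (including a
  synthetic parameter set with a *genuine* subcritical Hopf point used to
  validate the cycle machinery), a `paper-demo` report, and a `click` CLI.

## A note on fidelity

The worked-example parameter set bundled as `data/paper_section3.yaml`
reproduces the printed threshold (`R0 = 2.2606`), equilibria
(`(0.25, 0.625)` and `(1.3505, 1.1752)`), and focal number (`σ = 3.965`)
exactly. However, direct computation (closed-form and finite-difference
Jacobians agree) shows the smaller equilibrium is a **saddle**
(`det J < 0`) and the larger a **stable focus** — the side condition
`δ > 0` equals `det J < 0` at a trace-zero point, so it certifies a saddle
rather than a Hopf point, and no periodic orbit exists at these parameters.
The corresponding acceptance tests assert the original claims and fail with
explanatory messages; the cycle machinery itself is validated on the
synthetic fixture `subcritical_hopf_params()`, where a real unstable limit
cycle (period ≈ 6.07, winding number 1) is found with return-map residual
below 1e−7.

## CLI

```sh
sirstreat equilibria --config src/sirstreat/data/paper_section3.yaml
sirstreat stability  --config cfg.yaml --grid-n 50
sirstreat hopf       --config cfg.yaml --equilibrium-index 0 --tol 1e-3
sirstreat simulate   --config cfg.yaml --i0 1.0 --r0 1.0 --t-end 500 --out traj.csv
sirstreat cycle      --config cfg.yaml --equilibrium-index 0
sirstreat paper-demo --outdir out/
sirstreat gen-fixtures --regime R0_below_1 --seed 1 -n 10
```

Any of the eight parameters can be overridden with flags (`--A`, `--beta`,
…); overrides win over the config file. Exit codes: 0 ok, 1 analysis
failure (e.g. no cycle found), 2 bad input.

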