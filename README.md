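# pgbkin

Kinetic analysis of ligation-dependent conformational equilibria in
protoglobin CO binding.

## The problem

Protoglobin from the methanogenic archaeon *Methanosarcina acetivorans*
(*Ma*Pgb) binds and releases CO with distinctly biphasic kinetics. The
biphasicity arises not from two entry tunnels acting in parallel but from
two tertiary conformations in a ligation-dependent equilibrium: a
fast-rebinding, slow-dissociating state **r** favoured by ligation, and a
slow-rebinding, fast-dissociating state **t** favoured in the unliganded
protein. `pgbkin` implements the minimal mass-action reaction scheme that
quantifies this mechanism, together with the full analysis tool-chain used
around such schemes in time-resolved ligand-binding spectroscopy:

- a stiff ODE model of the 8-species reaction network (bound, primary
  docking site, secondary docking site, unliganded — each in the r and t
  conformations) with flash-photolysis, stopped-flow and NO-displacement
  initial conditions;
- global least-squares fitting of microscopic rate constants across
  experimental conditions (CO concentrations, temperatures) with shared
  parameters;
- maximum-entropy inversion of rebinding traces into lifetime
  distributions g(log τ);
- SVD of time-resolved difference-spectra matrices with autocorrelation
  component selection and stretched-exponential characterization of the
  relaxation course;
- Eyring analysis (ΔH‡, ΔS‡, ΔG‡) of rate-constant temperature series;
- a synthetic-data generator that emulates every input the pipeline
  consumes, so the whole analysis is testable without instrument data.

## The model

For each conformation x ∈ {r, t}, photolysed or solvent CO moves through

```
            k_g,x                k_out
  B_x  <────────────  P_x  ─────────────>  U_x + CO
       ────────────>       <─────────────
            k_d,x                k_in,x·[CO]
                       │ k_c/k_-c (r), k_d/k_-d (t)
                       ▼
                      S_x
```

with conformational exchange B_r⇌B_t (k₁/k₋₁), P_r⇌P_t (k₂/k₋₂) and
U_r⇌U_t (k₃/k₋₃); the secondary docking sites S_x neither exchange
conformation nor connect to the solvent. Apparent rate constants follow in
closed form:

- k_ON,x = k_in,x · k_g,x / (k_g,x + k_out) — entry times the probability
  that a docked ligand binds rather than escapes;
- k_OFF,x = k_d,x · k_out / (k_out + k_g,x) — dissociation times the
  probability that a released ligand escapes rather than rebinds.

Equilibrium constants K₁ = k₁/k₋₁, K₂ = k₂/k₋₂, K₃ = k₃/k₋₃ set the
liganded and unliganded conformational populations. The package ships the
fitted 20 °C rate sets for protein in solution and in the two silica-gel
encapsulation protocols as presets.

## Worked example

```python
import pgbkin as pk

rates = pk.SOLUTION_RATES                       # fitted 20 °C rate set
kon_r, kon_t = pk.derived_kon(rates)
koff_r, koff_t = pk.derived_koff(rates)
print(f"k_ON,r  = {kon_r:.3g} /M/s    k_ON,t  = {kon_t:.3g} /M/s")
print(f"k_OFF,r = {koff_r:.3g} /s       k_OFF,t = {koff_t:.3g} /s")

eq = pk.equilibrium_summary(rates)
print(f"K3 = {eq['K3']:.1f}  ->  unliganded slow-conformer fraction "
      f"{eq['f_t_unliganded']:.0%}")

# simulate a noisy 1 atm flash-photolysis trace and invert it
cond = pk.Conditions(temperature_K=293.15, co_atm=1.0, phi=1.0)
trace = pk.make_flash_trace(rates, cond, noise=2e-3, seed=1)

from pgbkin.mem import mem_invert, peak_report
for p in peak_report(mem_invert(trace)):
    print(f"lifetime band at {p.mode_tau:.2g} s  (area {p.area:.2f})")
```

prints

```
k_ON,r  = 2.09e+07 /M/s    k_ON,t  = 1.15e+06 /M/s
k_OFF,r = 0.0322 /s       k_OFF,t = 0.0808 /s
K3 = 3.0  ->  unliganded slow-conformer fraction 75%
lifetime band at 7.6e-09 s  (area 0.07)
lifetime band at 1e-05 s  (area 0.07)
lifetime band at 0.00019 s  (area 0.68)
```

The apparent on-rates span a factor ~20 between the two conformations —
the kinetic signature of the allosteric switch — while the off-rates
differ by ~2.5×. The lifetime distribution of the simulated trace shows
the geminate band at ~10 ns and the two CO-concentration-dependent
bimolecular bands (here ~10 µs and ~190 µs at 1 atm), with most amplitude
in the slow band.

A command-line interface mirrors the library:

```sh
pgbkin simulate flash --co-atm 1.0 --temp-C 20 --seed 3 --out flash.tsv
pgbkin mem flash.tsv --out dist.tsv
pgbkin svd spectra.tsv
pgbkin reproduce --seed 1
```

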