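# tmesense

ODE modeling of engineered *E. coli* Nissle 1917 (EcN) biosensors that read
the tumor microenvironment — elevated lactate, low pH, and hypoxia — through
the inducible promoters pLldR, pCadC and pPepT, amplify the signal through an
irreversible serine-integrase (TP901) "XOR" switch, and optionally destroy
their host through the phage lysis gene φX174E.

The package is for synthetic biologists and modelers who want to simulate,
calibrate and stress-test these circuits *in silico* before committing to
wet-lab characterization: it ships a calibrated default parameterization of
all nine promoter × topology strains, a stiff-capable simulator for time
courses, dose-responses and consortia, a least-squares calibrator against
end-point anchors, and a synthetic plate-reader data generator for
parameter-recovery studies.

## Model

Each strain is one of three topologies: **DIRECT** (sensing promoter →
mRFP), **SWITCH** (sensing promoter → integrase → terminator inversion →
strong constitutive promoter pP7 → mRFP) and **SWITCH_LYSIS** (as SWITCH,
plus φX174E co-expressed from the sensing promoter). The state of a culture
is (N_u, N_f, R, E, D): unflipped and flipped live cell densities, per-cell
reporter and lysis-protein levels, and lysed-cell debris. With promoter
activity A(u) (a Hill function of the strain's signal channel: lactate in
mM, [H⁺] = 10^(−pH) in M, or O₂ in %), nutrient factor
φ = max(1 − (N_u+N_f+D)/K, 0) and growth rate μ = r·φ:

    dN_u/dt = μ N_u − k_flip (A(u)/γ_I) φ N_u − δ(E) N_u
    dN_f/dt = μ N_f + k_flip (A(u)/γ_I) φ N_u − δ(E) N_f
    dR/dt   = syn_R φ − (γ_R + μ) R
    dE/dt   = α_E A(u) φ − (γ_E + μ) E
    dD/dt   = δ(E) (N_u + N_f) − γ_D D

where syn_R = g·A(u) for DIRECT and α_P7 for SWITCH topologies, and
δ(E) = δ_max E^h / (K_E^h + E^h) is the lysis death rate. The plate-reader
observables are OD600 = N_u + N_f + c_D·D and the background-subtracted,
OD-normalized fluorescence (R·N_f or R·N_u per topology, divided by OD600),
matching the standard mRFP/OD600 normalization. See `docs/methods.md` for
assumptions, units and numerical choices.

## Worked example

```python
import tmesense as tm

strain = tm.default_strain("pLldR", "SWITCH")          # calibrated lactate sensor
env = tm.EnvironmentSignal(lactate=10.0)               # 10 mM lactate, pH 7.3, 20% O2
traj = tm.simulate_time_course(strain, env, horizon=150.0)
s = tm.summarize(traj)
print(f"48 h readout: {traj.value_at(48.0):.1f} A.U.")
print(f"peak {s.peak_value:.1f} A.U. at {s.peak_time:.1f} h; "
      f"detectable to {s.persistence_time:.1f} h")
```

prints

```
48 h readout: 120.0 A.U.
peak 286.0 A.U. at 18.0 h; detectable to 132.0 h
```

— the amplified lactate sensor reads 120 A.U. at the 48 h end point (the
same strain without the switch reads 70.0 A.U.), peaks about 18 h after
induction, and stays above the calibrated detection threshold until 132 h.
Fold amplification for the other channels:

```python
tm.fold_change("pCadC", tm.EnvironmentSignal(pH=5.3))   # 1.90-fold
tm.fold_change("pPepT", tm.EnvironmentSignal(oxygen=0)) # 2.80-fold
```

The same operations are available from the shell:

```bash
tmesense simulate --out runs/switch --horizon 150
tmesense dose --out runs/dose --grid 0,0.1,1,5,10
tmesense generate --out runs/plate --seed 1
tmesense recover --out runs/recovery --seed 1
```

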