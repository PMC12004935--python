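# vescharge

Single-vesicle quantification of membrane surface charge from the binding
of a cholesterol-anchored DNA probe.

Giant unilamellar vesicles (GUVs) are the standard chassis for synthetic
cells, but the surface charge of an individual vesicle — set by its anionic
lipid content — is hard to read out in situ. `vescharge` implements an
optical assay for it: a 48-bp DNA duplex carrying one cholesterol anchor
and one fluorophore partitions onto the membrane, and because the duplex is
itself anionic (net charge −24e), its binding constant drops exponentially
with membrane charge. Measuring per-vesicle binding therefore measures
per-vesicle surface charge, repulsion energy and, through a screened
electrostatic model, surface potential.

## The model

Binding follows a two-state Langmuir isotherm in the Boltzmann-adjusted
free concentration:

    [DNA]_mem = [DNA]_max · K_B,int [DNA]_adj / (1 + K_B,int [DNA]_adj)
    [DNA]_adj = [DNA]_free · exp(−ε_elec / kT)

so that the *effective* binding constant on a charged membrane is

    K_B = K_B,int · exp(−Δε_elec / kT),

with `[DNA]_mem` the bound probe in mol % (DNA per 100 lipids), saturating
at `[DNA]_max`, and `Δε_elec` the extra electrostatic repulsion relative to
a neutral membrane. Empirically K_B decays mono-exponentially with the
anionic-lipid mole fraction n_PG:

    K_B(n_PG) = K_B0 · exp(−B · n_PG).

The repulsion energy of the probe a distance `d` from the slipping plane is
screened over the Debye length λ = 1/κ:

    Δε_elec = −q_DNA · e · Δφ · exp(−κ d) / kT,

linear in the (zeta) potential at fixed `d`, which lets a one-parameter fit
locate the probe's charge centre relative to the slipping plane.

The package covers the full chain: synthetic micrograph/population
generation (`synthetic`), FIJI-style annulus intensity measurement
(`imaging`), linear fluorescence calibration (`calibration`), isotherm /
charge-law / repulsion-energy inference (`binding`), Debye–Grahame
electrostatics and the probe-distance fit (`electrostatics`), microfluidic
flow-rate composition arithmetic with on-chip vs off-chip validation
(`mixing`), and a config-driven orchestration of all stages (`pipeline`,
plus a thin `vescharge` CLI).

## Worked example

`examples/01_binding_isotherm.py` generates a titration of 1800 synthetic
vesicles (6 added-DNA levels × 300 vesicles, 30 % vesicle-to-vesicle spread
on K_B) at a known truth and refits the isotherm:

```
fitted K_B      = 4.77 +/- 0.06 per-uM  (truth 4.7)
fitted [DNA]max = 0.367 +/- 0.001 mol %  (truth 0.37)
from 1800 vesicles over 6 concentration levels
```

K_B is the probe's effective binding constant for this membrane (per µM of
free DNA) and `[DNA]max` its saturation coverage; both bracket the
generating truth within a few bootstrap standard errors. The other
examples cover the charge law (`02`, recovering B ≈ 3.2), the probe
separation (`03`, recovering d ≈ 1.93 nm from zeta/energy pairs), image
rendering and annulus re-measurement (`04`), mixing arithmetic (`05`), and
the full pipeline (`06`, or equivalently):

```bash
vescharge run-all --config examples/pipeline_config.json --seed 7 --out pipeline_demo
```

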