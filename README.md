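# lipoperm

Analysis toolkit for **liposomal dye-release permeation assays**: a forward
simulator of carboxyfluorescein (CF) release experiments and the fitting
chain that recovers membrane **permeability** `P` and the apparent
**membrane/water partition coefficient** `K` from fluorescence time
series — including binary **copermeation** screens (does a co-loaded drug
enhance or retard the probe's permeation?) and SAXS lamellar-spacing
utilities for checking vesicle lamellarity.

It is written for formulation scientists and membrane biophysicists who run
(or want to model) vesicle efflux assays: CF is encapsulated at a
self-quenching concentration, so only released, dilute dye fluoresces; a
temperature step across the bilayer melting point (T_m = 41.5 °C for the
DPPC:DPPG:cholesterol 75:10:15 membrane) starts the efflux, and Triton X-100
micellization at the end defines the 100% release level.

## Model

Two aqueous compartments exchange dye across a single bilayer with a
concentration driving force:

```
V_in  dc_in/dt  = −P(T) · A · (c_in − c_out)
V_out dc_out/dt = +P(T) · A · (c_in − c_out)
```

A membrane-bound pool `m_mem` is static (dark, non-permeating) until
Triton releases it. On an isothermal segment the exterior concentration is

```
c_out(t) = c_fin − a · exp(−b·t),      b = P·A·(V_in+V_out)/(V_in·V_out)
```

so a nonlinear regression of the release curve from the inflection point
onward yields `b`, hence `P = b·V_in·V_out / (A·(V_in+V_out))`, and the
plateau mass balance yields the partition coefficient

```
K = (c_triton − c_fin)/c_fin · V_aq/V_lip .
```

All volumes and the permeation area come from the vesicle size
distribution (log-normal; volume-mean diameter `d_v = Σnd⁴/Σnd³`, Sauter
diameter `d₃₂ = Σnd³/Σnd²`), the bilayer thickness (4.059 nm), and the
cuvette protocol (60 μL liposome stock at 3.5 mg/mL lipid + 1140 μL PBS).
Permeability switches between gel- and fluid-phase values across T_m via a
logistic interpolation.

## Worked example

```python
import lipoperm as lp

pop, protocol, calib = lp.LiposomePopulation(), lp.MixingProtocol(), lp.CalibrationCurve()
geom = lp.assay_geometry(pop, protocol)
kin  = lp.reference_kinetics()                      # P(40 °C)=1.4e-8 cm/s, K=2.9e4

trace = lp.generate_trace(lp.ExperimentRecipe("CF alone", seed=7),
                          kin, pop, protocol, calib)
fit = lp.fit_release(trace, calib, geom)
print(fit.P, fit.K)
```

prints (one noisy replicate):

```
rate constant b        : 4.564e-03 1/s
permeability P         : 1.342e-08 cm/s   (truth 1.400e-08)
partition coefficient K: 2.889e+04        (truth 2.900e+04)
log10 K                : 4.46
```

`b` is the first-order efflux rate at 40 °C, `P` the single-bilayer
permeability it implies for this geometry, and `K` the apparent
partitioning inferred from how far the thermal plateau sits below the
Triton level — log₁₀K ≈ 4.5, far above the probe's octanol/water value,
reflecting surface adsorption and dimerization counted by the mass
balance.

The `examples/` directory has one short script per capability: the
four-stage trace anatomy, the fitting chain, the copermeation panel
screen, SAXS spacing, and the enhancer/temperature-scan scenarios. A thin
CLI is also available:

```sh
lipoperm simulate --config cfg.yaml --out run/
lipoperm fit --traces run/ --config cfg.yaml --out run/
lipoperm compare --results run/ --reference "CF alone"
lipoperm saxs-fit --curve curve.csv --npeaks 2
```

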