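# mapfit

Multi-resolution density-guided flexible fitting of coarse-grained protein
models into 3-D cryo-EM density maps, with fluctuation-based map/model
validation and B-factor estimation.

## The problem

A cryo-EM reconstruction gives a density map Φ(**r**); a crystal structure or
homology model of the same molecule gives starting coordinates in a different
conformation.  Flexible fitting turns the map into a biasing potential

    V(r) = ζ [1 − (Φ(r) − Φ_thr)/(Φ_max − Φ_thr)]   for Φ ≥ Φ_thr,   V = ζ below,

so density maxima are energy minima, and runs molecular dynamics of the model
under U_total = U_MD + U_EM + U_SS, where U_EM = Σᵢ wᵢ V(**r**ᵢ) couples each
particle (weight wᵢ, by default its mass) to the map, U_MD is the internal
force field, and U_SS restrains secondary structure.

At high map resolution V is corrugated: a model that starts several Å away
gets trapped in a nearby wrong minimum.  `mapfit` implements the two standard
escapes:

* **Cascade fitting** — blur the map with a decreasing ladder of Gaussian
  half-widths σ₁ > σ₂ > … > 0 (blurring a Gaussian component of width s gives
  width √(s² + σ²)), fit sequentially through the ladder, each stage seeding
  the next, then anneal (ζ → 1, 300 K → 0 K).
* **Resolution-exchange fitting** — one replica per ladder rung running in
  parallel, with Metropolis swaps of neighboring maps:
  p = min(1, exp(−[E(xᵢ,σⱼ) + E(xⱼ,σᵢ) − E(xᵢ,σᵢ) − E(xⱼ,σⱼ)]/k_BT).

Validation tools score the result: global/local map-model correlation
(GCC/LCC), Fourier shell correlation and its resolution-range integral (iFSC,
in Å), half-map cross-validation against overfitting, per-bead RMSF profiles,
the quadratic B-factor relation B = 8π²/3·RMSF², Guinier estimation of the
map's overall B-factor, and RMSF-vs-B sharpening scans whose minimum locates
the optimal sharpening.

Everything runs at desk scale on a structure-based (Gō-like) Cα model — one
bead per residue — so a complete cascade fit of the packaged ~124-bead fixture
takes well under a minute on one CPU.

## Worked example

```python
import numpy as np
from mapfit import (SimConfig, make_schedule, run_cmdff, run_direct, rmsd, gcc)
from mapfit.synthetic import make_fixture

fx = make_fixture(seed=1)            # target conformer, 7 A-displaced search
                                     # model, 3 A synthetic map
print(round(rmsd(fx["search"], fx["target"]), 2))   # 6.97

schedule = make_schedule(5.0, 1.0)   # sigma = 5, 4, 3, 2, 1, 0 A
result = run_cmdff(fx["search"], fx["map"], schedule,
                   SimConfig(seed=1), reference=fx["target"])
for stage in result.stages:
    print(f"sigma={stage.sigma:.0f}  RMSD={stage.rmsd_to_reference:.2f}  "
          f"GCC={stage.gcc:.3f}")

direct = run_direct(fx["search"], fx["map"], SimConfig(seed=1),
                    reference=fx["target"])
print(f"direct final RMSD: {direct.final_rmsd:.2f}")
```

Output from this exact script:

```
6.97
sigma=5  RMSD=1.46  GCC=0.849
sigma=4  RMSD=1.44  GCC=0.867
sigma=3  RMSD=1.31  GCC=0.904
sigma=2  RMSD=0.91  GCC=0.959
sigma=1  RMSD=0.75  GCC=0.977
sigma=0  RMSD=0.69  GCC=0.981
direct final RMSD: 4.14
```

The cascade walks the model from 7 Å down to 0.7 Å of the target while the
per-stage map correlation climbs; a direct fit against the unblurred map gets
trapped around 4 Å.  The RMSD after the most-blurred stage alone is already
below 2 Å, and resolution exchange reaches the same end point in fewer
unblurred-map steps.

There is also a CLI over the same machinery:

```sh
mapfit make-fixture --seed 1 --out fixture/
mapfit fit --mode cascade --map fixture/map.mrc --model fixture/search.pdb \
    --reference fixture/target.pdb --sigma-start 5 --sigma-step 1 \
    --zeta 0.3 --seed 1 --out run/
mapfit validate --map fixture/map.mrc --model run/fitted.pdb \
    --localres fixture/localres.mrc --out report/
mapfit blur --map fixture/map.mrc --sigma 3 --out blurred.mrc
mapfit sharpen-scan --map fixture/map.mrc --model run/fitted.pdb \
    --b-range -200 0 25 --out scan/
```

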