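# statediagrams

State diagrams of carbohydrate food systems: curve fitting, the
maximal-freeze-concentration condition, and solute-composition mixture
models.

A state diagram maps the physical states of a solids–water food system
(glassy, rubbery, frozen, liquid) over the full solids-mass-fraction ×
temperature plane. It is the standard design chart for freezing, frozen
storage, freeze drying and spray drying of sugar-rich products such as
fruit juices: frozen-storage stability requires holding the product
between the glass transition Tg′ and the melting onset Tm′ of its
maximally freeze-concentrated phase, and collapse or stickiness in
drying is governed by the glass curve Tg(ws).

This package is written for food physical chemists and process
engineers who work with DSC (differential scanning calorimetry)
transition data for aqueous carbohydrate systems — here the six solutes
dominating fruit juices: fructose, glucose, sucrose, pectin, citric
acid, and maltodextrin (a high-molecular-weight cryoprotectant and
spray-drying carrier).

## Models

**Glass transition curve** — Gordon–Taylor equation, a weighted mean of
the anhydrous-solids transition Tgs and the amorphous-water transition
Tgw = −135 °C with interaction constant K:

    Tg(ws) = (ws·Tgs + K(1−ws)·Tgw) / (ws + K(1−ws))

**Freezing curve** — Chen freezing-point-depression equation with the
water-to-solids molecular-mass ratio E = λw/λs and unfreezable-water
ratio B (per unit solids); β = 1860 kg·K/kgmol and λw = 18.015 kg/kgmol
are physical constants of water:

    Tm(ws) = Tw + (β/λw)·ln[(1 − ws − B·ws) / (1 − ws − B·ws + E·ws)]

Both parameter pairs, (Tgs, K) and (E, B), are estimated from
moisture-series transition data by unweighted nonlinear least squares.

**Maximal-freeze-concentration condition (MFCC)** — Tg′ and Tm′ are the
averages of their replicate observations across moisture levels; ws′ is
the unique intersection of the Tm′ level with the strictly decreasing
Chen curve, found by bisection.

**Solute-composition models** — each of the seven quantities
(Tgs, K, E, B, Tg′, Tm′, ws′) is regressed on the dry-basis solute
fractions with a no-intercept Scheffé mixture polynomial

    y = Σᵢ aᵢ·Xᵢ + Σᵢ<ⱼ aᵢⱼ·Xᵢ·Xⱼ,   Σᵢ Xᵢ = 1,

fitted over a bundled 25-run D-optimal design and reduced by backward
elimination of interaction terms with coefficient p > 0.10. The fitted
models predict complete state diagrams for arbitrary juice/maltodextrin
blends.

## Worked example

```python
from statediagrams import (
    ChenParams, Composition, load_fixtures, predict_state_diagram, solve_ws_prime,
)

fx = load_fixtures()  # bundled design, fitted-parameter and model tables

# ws' for pure sucrose: intersect the averaged Tm' with its Chen curve
row = fx.table2_row(3)
chen = ChenParams(e=row["e"], b=row["b"])
print("sucrose ws':", round(solve_ws_prime(chen, row["tm_prime"]), 3))

# predicted state diagrams for a model juice base blended with maltodextrin
base = Composition(0.283, 0.283, 0.283, 0.075, 0.075, 0.0, sum_tol=2e-3)
for xm in (0.0, 0.3, 0.6):
    d = predict_state_diagram(base, xm, fx.table3)
    print(f"XM={xm:.1f}  Tgs={d.gt.tgs:6.1f} C  K={d.gt.k:.2f}  "
          f"Tg'={d.mfcc.tg_prime:6.1f} C  Tm'={d.mfcc.tm_prime:6.1f} C  "
          f"ws'={d.mfcc.ws_prime:.3f}")
```

prints

```
sucrose ws': 0.796
XM=0.0  Tgs=  28.3 C  K=3.20  Tg'= -56.4 C  Tm'= -38.3 C  ws'=0.719
XM=0.3  Tgs=  64.3 C  K=5.62  Tg'= -52.7 C  Tm'= -32.9 C  ws'=0.784
XM=0.6  Tgs=  64.9 C  K=6.06  Tg'= -46.5 C  Tm'= -25.1 C  ws'=0.794
```

Sucrose, with modest freezing-point depression (E = 0.0584), reaches a
highly concentrated unfrozen phase (ws′ = 0.796, i.e. only ~0.2 g
unfreezable water per g). Raising the maltodextrin fraction XM of the
juice base lifts the anhydrous glass transition, the frozen-phase
transitions Tg′ and Tm′, and ws′ — widening the safe frozen-storage
window, which is why maltodextrin is used as a cryoprotectant and
carrier agent.

The same stages are available from a shell:

```sh
statediag simulate --seed 3 --noise-sd 0 --out sim.csv
statediag diagram sim.csv --curves-out curves.csv
statediag predict --xm 0.3
statediag fixtures
```

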