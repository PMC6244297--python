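# glacialch4

A tested pipeline for quantifying methane production, oxidation and
release from a geothermally influenced glacier catchment. It is aimed at
glacial biogeochemists working with dissolved-gas field campaigns:
headspace-equilibrated water samples, sealed sediment incubations,
proglacial static chambers and dual stable-isotope (δ¹³C–δD)
measurements of CH₄.

The package covers five analysis stages plus a synthetic-data generator:

| stage | what it does |
| --- | --- |
| `headspace` | closed-vessel headspace → original aqueous CH₄ (mg l⁻¹) via the dimensionless Henry constant *H*ᶜᶜ = C_aq/C_g |
| `kinetics` | blank-corrected OLS rates: incubation potentials (fmol g⁻¹ dry h⁻¹) and chamber fluxes (µmol m⁻² day⁻¹) |
| `isotopes` | closed-system Rayleigh fractionation (fit, forward model, inversion), two-end-member mixing, source classification in δ¹³C–δD space |
| `budget` | catchment export, per-glaciated-area production capacity, upstream–downstream evasion and stream-area evasion flux |
| `fieldsummary` | site × melt-season-phase mean/range/n tables with day-of-year phase assignment |
| `synthetic` | campaign/incubation/chamber generators with ground-truth keys, each a measurable inverse of its analysis stage |

## The core model

Methanotrophic consumption of a finite CH₄ pool fractionates both
isotope systems. With *f* the fraction of methane remaining and α the
kinetic fractionation factor, the residual pool follows the
closed-system Rayleigh relation

```
α = [ ln((δX_t + 1000) / (δX_i + 1000)) / ln f  +  1 ]⁻¹
⇔  δX_t = (δX_i + 1000) · f^(1/α − 1) − 1000
```

applied independently to δ¹³C (α_C ≈ 1.019) and δD (α_D ≈ 1.197).
Because α_D ≫ α_C, oxidation drives samples along a steep trajectory in
δ¹³C–δD space — steeper than the mixing line between microbial and
geogenic end members — which is what lets the classifier separate
`oxidation_affected` samples from `mixed` ones.

The budget side is mole/mass bookkeeping: export = Q·C, converted to a
per-glaciated-area production capacity; evasion along the proglacial
reach from an upstream–downstream concentration balance, area-weighted
over the stream surface.

## Worked example

```python
from glacialch4 import (Scenario, CatchmentGeometry, budget_report,
                        rayleigh_alpha, rayleigh_residual, classify_source,
                        IsotopePair)

report = budget_report(
    [Scenario("summer", 50.0, concentration_mg_l=11.2, evasion=0.86),
     Scenario("winter", 10.0, concentration_mg_l=0.65, evasion=0.54)],
    CatchmentGeometry(),   # 78 km² glaciated, 4 km × 20 m stream reach
)
print(report[["scenario", "export_t_day", "production_mmol_m2_day",
              "evasive_t_day", "stream_flux_mol_m2_day"]].round(2).to_string(index=False))

dt = rayleigh_residual(-60.0, 1.019, 0.5)
print(f"residual delta13C after 50% oxidation: {dt:.1f} permil")
print(f"alpha recovered from that pair: {rayleigh_alpha(-60.0, dt, 0.5):.3f}")
print("upwelling mean classifies as:",
      classify_source(IsotopePair(-59.6, -323.7)))
```

prints

```
scenario  export_t_day  production_mmol_m2_day  evasive_t_day  stream_flux_mol_m2_day
  summer         48.38                   38.67          41.61                   32.43
  winter          0.56                    0.45           0.30                    0.24
residual delta13C after 50% oxidation: -47.8 permil
alpha recovered from that pair: 1.019
upwelling mean classifies as: microbial
```

Reading the budget rows: at a summer discharge of 50 m³ s⁻¹ carrying
11.2 mg l⁻¹ dissolved CH₄ the catchment exports ≈ 48 t CH₄ day⁻¹,
equivalent to ≈ 39 mmol CH₄ m⁻² day⁻¹ of production capacity under the
glaciated area; with 86 % evaded along the 4 km proglacial reach that is
≈ 42 t day⁻¹ to the atmosphere, or ≈ 32 mol m⁻² day⁻¹ of stream surface.
The Rayleigh lines show a −60 ‰ microbial source enriching to −47.8 ‰
after half the pool is oxidised at α_C = 1.019, and the subglacial
upwelling signature (−59.6 ‰, −323.7 ‰) falling squarely in the
microbial source field.

A `glacialch4` console script exposes the same stages as subcommands
(`equilibrate`, `rates`, `rayleigh`, `classify`, `summarize`, `budget`,
`simulate`); `glacialch4 simulate campaign --seed 3 --out DIR` writes a
synthetic field campaign with its ground-truth key.

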