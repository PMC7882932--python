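# traitspace

Position any plant — individual, population, species or community mean — in a
reference phenotypic trait space and compare it against the worldwide
background of plant form and function.

Six traits describe most of the functional variation among vascular plants:
adult plant height (H, m), stem specific density (SSD, mg/mm³), leaf area
(LA, mm²), leaf mass per area (LMA, g/m²), leaf nitrogen per unit mass
(Nmass, mg/g) and seed dry mass (SM, mg). Worldwide, about three-quarters of
their joint variation lies on a two-dimensional plane spanned by a
whole-plant **size** axis and the **leaf economics** axis (quick vs. slow
return on leaf investments). `traitspace` builds that plane as a PCA of
log10-transformed, globally centered and scaled reference trait values

    z_t = (log10(v_t) − m_t) / s_t,   scores = z · V

and projects user datasets into it as *supplementary (inactive)
individuals* — standardized with the **reference** means/SDs and multiplied
by the reference loadings V, so the background plane is never distorted by
the upload. Because the original worldwide dataset is not publicly deposited,
the package ships a calibrated synthetic generator that reproduces its
statistical structure (two dominant axes, worldwide log-scale trait ranges,
herb/shrub/tree/other growth forms); see `docs/methods.md`.

The toolkit covers: trait/growth-form subsetting with refitted PCAs,
occurrence-probability density surfaces and 0.50/0.95 highest-density
regions (overall or per growth form), biplots with a correlation circle,
paired trait boxplots, coordinate export with a metadata header, and CSV
dialects with configurable separator/decimal/missing markers.

## Worked example

```python
import pandas as pd
import traitspace as ts

ref = ts.generate_reference()          # 2,214 synthetic reference entities
space = ts.fit_space(ref)              # six traits, all growth forms

print("explained:", (space.explained * 100).round(1))
print(ts.trait_component_correlations(space).round(2).iloc[:, :2])
```

```
explained: [49.1 34.2  7.3  3.9  3.1  2.3]
        PC1   PC2
H      0.94 -0.07
SSD    0.66 -0.49
LA     0.87  0.26
LMA    0.07  0.94
Nmass -0.07 -0.93
SM     0.92  0.03
```

The first two components capture 83.3% of total variance. PC1 is the size
axis — height, seed mass and leaf area all correlate ≥ 0.87 with it — and
PC2 is the leaf economics axis, with LMA (0.94) opposing Nmass (−0.93).

Projecting two made-up entities (trait values in natural units, no prior
transformation):

```python
upload = pd.DataFrame({
    "entity_id": ["annual_herb", "old_oak"],
    "H": [0.3, 25.0], "SSD": [0.35, 0.65], "LA": [1200.0, 4500.0],
    "LMA": [35.0, 95.0], "Nmass": [28.0, 18.0], "SM": [0.8, 3200.0],
})
result = ts.project_entities(space, upload)
print(result.coordinates.round(2).iloc[:, :2])
```

```
    PC1   PC2
0 -0.66 -2.24
1  3.68 -1.15
```

The small annual sits left of center on the size axis with an acquisitive
(leaf-economics-fast, negative PC2) leaf strategy; the oak sits far right
among the large woody species. Entities with missing (`NA`) or nonpositive
trait values are excluded with a per-entity reason — no gap-filling is ever
performed — and a trait absent as a whole column means the space must be
refitted without it.

### Command line

The same workflow as shell commands:

```sh
traitspace simulate --out reference.csv
traitspace fit --reference reference.csv --traits H,LA,LMA,SM \
               --growth-forms herb --out herbspace.json
traitspace project --space herbspace.json --entities mydata.csv \
               --sep ';' --decimal ',' --out coordinates.csv
traitspace plot --space herbspace.json --entities mydata.csv \
               --group-col stage --format svg --out figure.svg
```

`coordinates.csv` starts with `#` metadata lines naming the traits and the
number of reference entities behind the PCA, then repeats the uploaded table
with `PC1…PCp` appended (excluded rows keep missing coordinate cells).

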