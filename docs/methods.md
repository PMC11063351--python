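# Methods

## The problem

Restaurant and cafeteria dishes rarely come with analysed nutrient data,
yet labeling rules ask for energy, fat, sodium (and optionally protein
and carbohydrate) per 100 g of the *cooked* dish. The obvious route —
multiply each raw ingredient's per-100 g composition by its mass and sum
— fails in two ways: the dish's mass changes during cooking (rice roughly
doubles in weight when steamed; roast meat loses a third), and cooking
itself moves nutrients (frying adds fat, boiling leaches solutes, braising
adds sodium from the sauce). catercalc models both effects.

## The calculation model

For a dish with ingredients $i = 1..n$, each with edible raw mass $m_i$
(purchased mass × edible fraction) and raw composition $c_i$ (g per 100 g
edible portion), the absolute nutrient totals are

$$\mathrm{Sum} = \sum_i c_i \, m_i / 100 \; \times k_{(g_i,\,\mathrm{method},\,\mathrm{nutrient})}\;\;(+\ \text{seasoning fat/sodium in g}),$$

where $k$ is a multiplicative cooking-method correction factor keyed by
the ingredient's food category $g_i$, the dish's cooking method, and the
nutrient ($k \equiv 1$ when no correction database is supplied). Weighed
seasonings contribute absolute masses through a per-100 g composition
table: fat from oil (times a configurable uptake fraction, default 1.0 —
oil not absorbed by the food is still charged to the dish), sodium from
salt (39.3 g/100 g, NaCl stoichiometry), soy sauce (5.8) and chicken
essence (20), and sugar's carbohydrate (99.9, toggleable).

The per-100 g-cooked concentration is then

$$C = \mathrm{Sum} \,/\, W \times 100,$$

with $W$ the cooked dish weight: the measured weight when the recipe
records one, otherwise estimated from the **raw-to-cooked ratio**
$r = \text{raw edible mass} / \text{cooked mass}$ as
$W = (\sum_i m_i + \sum \text{seasoning mass}) / r$, using the ratio of
the *main* ingredient (largest edible raw mass). $r < 1$ means mass gain
(water uptake), $r > 1$ mass loss. Nutrient mass is conserved from raw to
cooked, so $C \times W / 100$ always reconstructs the raw-side totals
exactly; for a single-ingredient dish with estimated weight this collapses
to the closed form $C = c \times r \times k$.

The correction factor is applied **per recipe line** by that line's
category. For single-category dishes this is identical to scaling the
dish totals; for mixed dishes it is the only reading under which the
factor keyed by (category, method, nutrient) is well defined.

### Energy and NRV%

Label energy is computed from per-100 g values with configurable
per-gram factors, default 17/37/17 kJ/g for protein/fat/carbohydrate
(the convention of Chinese labeling practice), converted at
1 kcal = 4.184 kJ; the classic 4/9/4 kcal factors are available through
`EnergyFactors(4, 9, 4, unit="kcal")`. NRV% is 100 × amount / daily
reference, with sodium converted g→mg before dividing. Default
references: energy 8 400 kJ, protein 60 g, fat 60 g, carbohydrate 300 g,
sodium 2 000 mg — all configurable, and computable on a per-100 g basis
(label default) or on whole-dish totals.

## The composition database

Ingredients carry a two-tier label (general category → subclass, e.g.
meat → chicken breast). Per group, a **representative value** is the
unweighted arithmetic mean of members' per-100 g nutrients; optional
fields (water, ash) are averaged over the members that carry them, with
per-nutrient counts recorded. Resolution of a recipe ingredient proceeds
exact id/name match → declared-subclass representative →
declared-category representative, and never fabricates values: the
returned vector is bit-identical to a stored record or representative.
Unknown varieties of a known food type therefore price in at their
group's mean. Sodium is stored in g/100 g throughout (matching how the
packaged dish-level tables print it); input tables may instead provide a
`sodium_mg` column.

Carbohydrate by difference is
`total − water − ash − protein − fat`; a deficit of at most 0.5 g is
clamped to 0 with a logged diagnostic (measurement noise in proximates),
a larger deficit is an input inconsistency and raises. The same 0.5 g
tolerance bounds the proximate-sum invariant on per-100 g vectors.

## Correction factors

Given paired per-100 g values — model-**calculated** and
laboratory-**detected** — for a set of dishes, each cell's ratio
calculated/detected is screened: ratios **≤ 0.5 or ≥ 2.0 (inclusive)**
flag a badly missed cell. Flags are evaluated on the *unrounded* ratio;
display values are rounded half-up to 2 dp, so a printed "0.50\*" can
carry an unrounded 0.4967. A calculated value of exactly 0 gives ratio 0,
flagged; detected 0 with calculated > 0 gives an undefined, flagged cell.

For each (category, method, nutrient) key with at least one flagged cell,
the factor is the mean (or median) of detected/calculated over the key's
cells with calculated > 0; cells with calculated = 0 are excluded (the
quotient is undefined) and logged. Unflagged keys keep factor 1.0,
inactive; a flagged key with no aggregable cells stays at 1.0 with a
warning. Pooling across dishes within a key is deliberate: factors
describe a (food type, method) effect, not a dish. On the packaged data
this yields 188 keys, 88 active, and applying them reduces the overall
mean absolute percentage error of calculated vs detected from 66.6% to
18.6% (recomputed by `catercalc validate` and the acceptance script —
nothing is hard-coded).

Validation reports MAE and MAPE (over cells with detected > 0) per
nutrient and pooled, before and after correction, flagging any nutrient
whose error increased. By construction a singleton-support factor
reproduces its training cell exactly; on fresh data the factors are an
honest shrinkage of a systematic bias, not a fit.

## Packaged reference tables

Five plain-CSV tables transcribed from a published cooking study of
common Chinese dishes ship inside the package: the sampling plan
(15 rows; its printed per-row counts sum to 144 although the printed
total says 150 — kept as printed), 44 raw-to-cooked ratios, 48 dishes'
detected values (means and SDs of replicates; only means enter any
computation), the matching calculated values, and the printed ratio table
with its screening marks. Label drift between the source tables (one fish
category printed as "Scallops" in the detected table and "Hairtail" in
the calculated one; two dishes with differing method labels) is preserved
verbatim; pairing is positional, guarded by a category block-structure
check, with output rows labelled from the calculated table.

## Synthetic data

The composition generator emulates a food composition table for the 15
ingredient types of the sampling plan. Its per-subclass means are
realistic raw compositions chosen once (e.g. raw rice: protein 7.4, fat
0.8, carbohydrate 77.2, sodium 0.004 g/100 g); they are a synthetic
stand-in, not transcribed from any reference table. Each nutrient is
drawn N(μ, (0.08 μ)²) truncated at 0; water is filled by difference so
every row satisfies the proximate-sum invariant exactly, and the rare
draw whose macros alone exceed 100 g is rescaled onto the simplex. The
generator does not emulate covariance between nutrients, regional
variety effects, or skewed trace-nutrient distributions — so tests built
on it demonstrate the *pipeline's* statistical behaviour (mean recovery,
bias recovery), not the field accuracy of any real composition table.

The paired generator plants a known multiplicative bias:
detected = calculated / b × (1 + ε), ε ~ N(0, σ) with σ = 0.05 and
20 dishes per key by default. The mean of detected/calculated then
estimates 1/b with relative standard error σ/√20 ≈ 1.1%, which is what
makes the 5%-recovery acceptance check meaningful rather than lucky.
Everything is driven by one mandatory seed; identical specs produce
byte-identical tables.

## Numerical choices and problem sizes

- Display rounding: half-up (`decimal`), 2 dp for ratio cells, 1 dp for
  g/100 g label values, integers for kJ and NRV%. Internal math is never
  rounded.
- Conservation and closed-form properties are exercised on 1 000 seeded
  random dishes each (tolerance 1e-9 g absolute / 1e-9 relative);
  representative recovery on 200 records per subclass (3-SE band);
  bias recovery on 20 dishes per key. These sizes put the statistical
  checks well inside their detection power while the whole suite runs in
  a couple of seconds.
- Zero-mass recipe lines are dropped before resolution; a dish whose
  estimated cooked weight is 0 raises rather than dividing by zero.
- Category lookups tolerate singular/plural drift ("potato" vs
  "Potatoes"); cooking-method labels are normalised through a closed
  enumeration ("Stewing (with soy sauce)" → `stewing`).

## Known limitations

- Correction factors are point estimates; no uncertainty intervals and
  no regression-based alternative.
- Cooked-weight estimation for multi-ingredient dishes borrows the main
  ingredient's ratio for the whole dish — a deliberate simplification;
  mixtures have no measured ratios.
- Resolution is exact-string plus declared group; no fuzzy name
  matching.
- Only fat, protein, carbohydrate and sodium are modeled; vitamins,
  minerals and sugars beyond added sucrose are out of scope.
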