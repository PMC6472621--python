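# Methods

## Scope and intent

`defencesim` is a desk-scale, individual-based reimplementation of a
growth–defence trade-off experiment in silico: mono- and mixed stands of
defended and undefended annual plants compete for light while paying
metabolic costs for defence and suffering rank-structured herbivore damage.
It deliberately replaces a full 3-D functional–structural plant model with a
mean-field layered canopy, so absolute yields are not comparable to any
field calibration; all conclusions are drawn from *relative* metrics
(percentage cost and benefit against matched baselines) and from the
qualitative structure of the treatment responses.

## Environment

Weather is a fixed pair of seasonal sinusoids (no year-to-year or day-to-day
noise): mean air temperature 10 °C with 8 °C amplitude peaking mid-July, and
incident PAR 6 ± 4 MJ m⁻² d⁻¹ peaking at midsummer — a serviceable stand-in
for average Dutch conditions at ~52° N. A CSV override (`doy, temp, par`)
accepts user weather. Thermal time accumulates as growing degree days above
a base temperature of 0 °C (common for brassicas); the season, 31 March to
2 August, spans 124 daily steps and ≈ 1 830 GDD. Both drivers being
deterministic, the only stochasticity anywhere in the simulator is the
seeded lognormal jitter (σ = 0.05) on initial seedling size.

## Plant growth and canopy

Each plant carries ranked leaves (rank 1 = oldest), a stem and a seed pool.
Organ initiation is phyllochron-driven (30 °C·d per leaf) and stops at
flowering (600 °C·d after emergence), giving ≈ 22 leaves. Potential lamina
biomass rises linearly with rank from 0.5× to 1.5× the mean of 0.12 g —
the bolting-crucifer pattern in which later leaves are larger — so the
mature canopy is top-heavy and damage to young leaves is genuinely costly.
Leaf area is strictly biomass × SLA (0.02 m² g⁻¹).

Light: the plot (16 plants, 4 × 4, 100 plants m⁻², i.e. 0.16 m² ground) is
treated as horizontally homogeneous; this is the mean-field analogue of
averaging every plant over hundreds of cloned plot copies, and removes
border effects by construction. The canopy is discretised into 20 layers
between the ground and the tallest leaf; light attenuates downward by
Beer–Lambert extinction (k = 0.7) per layer and the absorbed fraction is
split among plants in proportion to their leaf area in that layer. Because
leaves are inserted at the plant's height at initiation, taller plants place
leaves in higher layers and intercept disproportionately — size-asymmetric
competition, the central engine of the ecological costs studied here. A
leaf-sequential closed form (every leaf its own stratum) is used in the test
suite as an independent fine-discretisation oracle.

Carbon: assimilation is linear in intercepted PAR (LUE 3 g MJ⁻¹).
Spending order within a day is strict: (1) defence tax (defended genotypes
only, `(1 − D/100)`, taken from gross assimilate — the model assumes the
defence machinery is paid before any somatic allocation); (2) maintenance of
standing leaf + stem biomass (0.015 g g⁻¹ d⁻¹, capped at income so biomass
is never respired away; shortfalls are flagged, not carried); (3) a seed
share that ramps linearly from 0 at flowering to 1 over 300 °C·d; (4)
vegetative demands — leaf expansion toward each leaf's (possibly
herbivory-reduced) ceiling with a saturating thermal kernel (τ = 80 °C·d),
plus a stem share fixed at 30% of satisfied demand. Of any vegetative
surplus beyond demand, 25% feeds further stem (bolting) growth and the rest
is booked as belowground allocation outside the aboveground canopy model.
Height follows stem biomass allometrically (0.25 · stem^0.5 m). Every gram
is ledgered; whole-run conservation closes to ~1e-12 relative and is
asserted at 1e-6.

The surplus split deserves a note, as it was the one genuinely free
structural choice with qualitative consequences. Sending no surplus to the
stem makes leaf ceilings bind early, genotype sizes converge, and
intergenotypic competition nearly vanishes; sending all of it produces
runaway height races and competitive exclusion at even 5% defence
investment. The 25% default was calibrated once against the qualitative
competition regime of the study system — a disproportionate (but not
annihilating) mixture cost that herbivory progressively erodes — and left
fixed thereafter.

## Herbivory and defence

Damage is a leaf-level removal rate per GDD: logistic over relative rank
with slope `10·(h − (1 − h))`, scaled by leaf biomass, the base rate `c`
and the defence reduction `(1 − d/100)`. The exponent grouping was chosen
so that (a) h = 0.2 yields slope −6 exactly, matching the printed
undefended form; (b) h = 0.5 is uniform; (c) h ↔ 1 − h mirrors the profile
in r ↔ 1 − r. Removal per day is capped at the leaf's biomass. Damage is a
function of each plant's own leaves only — herbivores do not relocate in
response to neighbour defence. A plant with a single leaf takes r = 0.5
(the rank map is 0/0 there; the midpoint is the least-informative choice).
Herbivory acts after growth within the day.

Damage reduces the leaf's *potential* biomass along with its realised
biomass. The default mode is proportional: losing a fraction of the current
lamina forfeits the same fraction of its remaining expansion capacity, so
damage to a young, expanding leaf destroys far more future growth than the
same grams taken from a mature leaf. An absolute mode (ceiling drops by the
grams removed) is available as a config flag; under that mode young-leaf
damage carries almost no future cost, and the net cost–benefit ordering of
the damage-distribution treatments degenerates, which is why proportional
is the default.

## Scenarios, replication and seeds

Stand layouts: monostands, or 50:50 checkerboard mixtures (the spatial
arrangement is a design choice; under the mean-field canopy only the
genotype counts matter). Named suites enumerate the three factorial
designs: costs (D ∈ {5,…,25}%, no benefit, three herbivory regimes, both
stand types, plus undefended controls), benefits (d ∈ {0,…,50}%,
h ∈ {0.2, 0.5, 0.8}, low/high herbivory, with the defence tax waived), and
net costs-versus-benefits (mixtures at D = 15%, full (d, h) × (low, high)
factorial). Replicates (default 10) differ only in the initial-size jitter;
per-run seeds derive from one base seed via a counter-based spawn-key
scheme (cell index, replicate index), so any cell re-runs independently and
bit-identically.

## Statistics

Costs and benefits are computed per replicate (defended-genotype mean
against its baseline, paired by replicate; within-run undefended means for
mixtures) and summarised as mean ± SE. The one-way ANOVA is computed from
between/within sums of squares, with the p-value from the F distribution
via the regularised incomplete beta function; it is cross-checked in the
test suite against the t² identity and a 10⁵-permutation null. Tipping
points are read off the d-grid as the smallest level with positive mean net
benefit (no interpolation: the design is a grid, and grid resolution is the
honest precision).

## What the generator does and does not emulate

The synthetic stand captures: thermal-time development, size-asymmetric
light competition, source–sink allocation with a defence tax, biomass- and
rank-structured herbivore removal, and replicate variance from initial-size
heterogeneity. It does not capture: 3-D architecture and its plastic
responses (shade avoidance, R:FR signalling), root/water/nutrient
competition, herbivore movement or population dynamics, induced defence, or
real weather. Passing pattern tests therefore demonstrate that the stated
mechanisms are sufficient to generate the qualitative treatment structure —
not that the magnitudes transfer to field stands.

## Numerical choices and degenerate inputs

Tolerances: mass-balance assertions at 1e-6 relative (observed closure
~1e-12); equation identities at ~1e-13 relative. Canopy layer count (20) is
a discretisation convenience; per-plant totals are conserved at any layer
count and the fine-layer oracle bounds the error. Zero total leaf area
intercepts nothing; empty layers transmit fully. Non-finite plant state
aborts a run with day/plant context. Yields are deterministic given
(config, seed); with jitter disabled, symmetric monostands give
bit-identical yields across plants.

## Desk-scale problem sizes

The test suite runs the cost design at 10 replicates and the full net
factorial at 5 replicates with fixed seeds; a single 124-day, 16-plant run
takes ~0.1 s, the whole suite a few minutes. These sizes were chosen as the
package's standard desk-scale configuration; all grids and replicate counts
are arguments.

## Known limitations

Absolute yields depend on invented physiological constants and are not
field-calibrated. The mean-field canopy underestimates local spatial
structure (a suppressed plant next to a dominant neighbour fares worse in
reality than in a homogenised canopy). Ecological equalisation by herbivory
can overshoot: under high pressure the mixture cost can drop slightly below
the monostand cost, where the reference system reports statistical
indistinguishability. The ANOVA treats plants within a plot as independent
observations, ignoring within-plot correlation, exactly as simple one-way
designs do.
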