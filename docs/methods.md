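# Methods

## Scope and data model

The package simulates a single mother-machine-style lineage: one daughter
is followed after every division, giving one record per generation. Units
are arbitrary (length in µm-like units, time in minutes-like units); all
models are scale-free and no unit conversion is performed.

Each `GenerationRecord` carries the elongation rate λ (length grows as
`exp(λt)`), the realized doubling time τ, birth and division sizes S_b and
S_d, the per-origin initiation size s_i attributed to this generation's
division, the total size at initiation S_i, the initiation-to-division
interval τ_cyc, the within-generation initiation timing a_i, the three
adder increments δ_ii, δ_id, Δ_d = S_d − S_b, and the division ratio.
Lineage files are TSV/CSV with exactly these column names and a
`# model=…; seed=…; burn_in=…` / `# params={…}` comment header.

## Attribution of initiation events (overlapping cycles)

When τ_cyc exceeds τ, the initiation that triggers division *n* occurred
in an ancestor generation (overlapping cycles; p+1 concurrent cycles with
p = ⌊τ_cyc/τ⌋). The simulators attribute each initiation both ways:

* **by time** (sHC, IA — τ_cyc is drawn): the event sits τ_cyc before the
  division on the lineage's wall clock; the generation m whose span
  contains it receives a_i, and g = n − m;
* **by size** (RDA, IDA, CCCP — timing is emergent): the ancestor reached
  total size 2^g·s_i(n) at the initiation; the walk back doubles the
  per-origin target once per generation until it falls inside an
  ancestor's [S_b, S_d] span.

In both cases S_i = 2^g·s_i, reflecting 2^g origins at initiation.
Initiations that precede the recorded lineage (early generations) leave
NaN entries, which the burn-in removes; when two initiations land in one
generation only the latest a_i is kept. Because each division size is
attributed exactly one initiation size, the per-origin identity
δ_id = (S_d − s_i)/2 holds for any number of overlapping cycles; the
generalized initiation-adder increment is δ_ii(n) = s_i(n+1) − r·s_i(n)
with division ratio r (= ½ for symmetric division). In the mechanistic
threshold model both event times are known, so the k-th initiation is
paired with the k-th subsequent division directly.

## Stochastic conventions

* One integer seed spawns a named independent RNG substream per stochastic
  variable (`SeedSequence(seed, spawn_key=(crc32(name),))`), so adding or
  toggling a variable never perturbs another's draws, and the same seed
  reproduces a lineage bit-for-bit.
* Gaussian draws of positive quantities are rejection-resampled into the
  positive domain, capped at 100 attempts per draw before an error naming
  the variable. At the CVs the models are meant for (≲ 0.2) the truncated
  mass is negligible and the draws remain effectively Gaussian.
* Septum noise: the division ratio is Gaussian(½, `septum_sd`) truncated
  to [0.35, 0.65]; the default is 0 (perfectly symmetric). Exposing it
  lets users reproduce how septum-position variance can restore
  adder-like correlations in otherwise sizer-skewed models.
* **Rare timing inconsistencies.** The sHC/IA recursions draw S_d directly
  from (λ, τ_cyc, s_i), so deep noise tails can realize S_d ≤ S_b
  (≈ 0.3% of generations at 10% CVs). Conditioning the draws away from
  such events would couple consecutive generations and bias the sizer
  correlation upward by about +0.012 — comparable to the Monte-Carlo
  tolerance — so sizes are kept exactly as drawn and only the wall clock
  is floored at 0.1% of a mean doubling time for the affected generations
  (count reported in `lineage.info["n_tau_floored"]`). Size statistics are
  therefore exact; timing statistics are approximate at the per-mille
  level.

### sHC mother-daughter coupling

`rho_i_md` and `rho_alpha_md` impose lag-1 Pearson correlations on s_i and
on α = exp(λτ_cyc) through stationary AR(1) chains on the standardized
variables, x(n+1) = ρx(n) + √(1−ρ²)ε. For α the chain runs on ln α with
the exact log-moments of the product of two independent Gaussians and a
lognormal-corrected coefficient, so the realized Pearson correlation of α
itself equals the requested value; τ_cyc is then recovered as ln α/λ with
λ drawn independently (its marginal is matched through the log-moments,
not exactly Gaussian in this mode). `cross_corr` draws (λ, τ_cyc, s_i)
from a joint Gaussian instead (PSD-checked) and cannot be combined with
the mother-daughter options.

### Initiator-threshold model

Balanced biosynthesis is integrated on a grid dt ≤ τ/200 (default τ/250):
each pool gains c*·dV per step, optionally with counting noise of scale
`production_noise`·√(c*dV) (1 ≈ Poisson). Division fires at N0 copies;
initiation fires all origins at (#oriC)·N0_init and resets its pool; both
pools and the origin count are partitioned at division (deterministic
halving by default, binomial optionally). A single shared threshold for
both processes cannot be steady-state consistent (the per-origin
initiation size 2·N0/c* would exceed the division size N0/c*), so the
initiation threshold is a separate parameter, defaulting to
N0_init = 0.35·N0, which places initiation mid-generation in the
non-overlapping regime. Event times are resolved at step ends, so timing
quantities carry an O(dt) discretization error.

## Closed-form predictions and their domains

`predict_correlations` implements the steady-state homeostasis
correlations: IDA (½, ½, 0) unconditionally; RDA
ρ_d = ½(1+3σ_id²/σ_ii²)⁻¹ and ρ_id = (1+3σ_id²/σ_ii²)^{−1/2}; IA/sHC in
terms of the CVs η_i (of s_i) and η_α (of α) with denominator
η_i²+η_α²+η_i²η_α², and ρ_id = η_i/√(η_i²+η_α²+η_i²η_α²) — the square
root spans the full denominator, a placement confirmed both analytically
(from S_d = s_i·α with independent factors) and against simulation.

The CCCP entries are expressed in log-size moments (μ_H, σ_H, μ_R, σ_R of
the two division-size candidates and σ_i of ln s_i), which are emergent
and must be measured from simulation. These formulas neglect the coupling
introduced by the max() branch selection: validated against simulation,
they agree within Monte-Carlo error only when one branch dominates
(f ≲ 0.01 or f ≳ 0.99); already at f ≈ 0.1 the measured ρ_id exceeds the
prediction by ≈ 0.05. The oracle tests therefore target the weakly-mixed
regimes, and mixed-f predictions should be treated as qualitative. The
cycle-duration formula τ_cyc = (1−f)C + f·2(B−A)/λ inherits the
⟨ln x⟩ ≈ ln⟨x⟩ approximation and is checked at 5% tolerance.

## The 18-variable panel

The I-value enumeration runs over a fixed, documented panel of 18
physiological variables: the 11 base observables {λ, τ, τ_cyc, a_i, S_b,
S_d, s_i, S_i, Δ_d, δ_ii, δ_id} plus 7 derived quantities {S_d/S_b,
s_i/S_b, λτ_cyc, λτ, δ_id/δ_ii, Δ_d/S_b, τ_cyc−τ} spanning sizes, added
sizes, durations and dimensionless ratios. The exact composition is a
package choice (a rich, fixed panel is what the enumeration argument
needs, not one specific list); swapping members changes individual ranks
but not the qualitative conclusion that many non-model quadruples outrank
the model quadruples. The sHC and IA quadruples {λ, τ_cyc, s_i, S_b} and
{λ, τ_cyc, δ_ii, s_i} follow the rule "control parameters plus the extra
variables entering the defining correlations" and are likewise an
interpretation; the RDA and IDA quadruples are canonical.

## Statistical conventions

Pearson coefficients come from complete pairs (NaN pairs dropped pairwise,
never imputed); zero-variance series raise an error rather than returning
0. Standard errors are reported on the Fisher-z scale (1/√(n−3)), and the
repo-wide stochastic tolerance is |z(measured) − z(predicted)| ≤ 3 SE.
The I-value uses complete cases across its variable set so the sample
correlation matrix is positive semi-definite, guaranteeing 0 ≤ I ≤ 1;
determinants within 1e-12 of zero (including tiny negatives from
round-off) are clipped to exactly 0. Model ranking refuses to compare
variable sets of different sizes — determinants of different-sized
correlation matrices are not commensurable, which is precisely the
limitation that makes 4-variable (RDA) vs 5-variable (IDA) I-value
comparisons meaningless. A warning is emitted when the data indicate
overlapping cycles (p ≥ 1), where the 4-variable analysis was not
originally intended to apply. No multiple-testing correction is applied:
the suite is descriptive.

## Reference conditions and problem sizes

Defaults emulate moderately fast growth: τ = 30 (λ = ln2/30), τ_cyc = 45
(one extra concurrent cycle), mean sizes of order one, and 10% CVs on all
stochastic variables — the regime in which the steady-state formulas are
derived and mother-machine datasets typically sit. Correlation checks use
50,000-generation lineages (Fisher-z SE ≈ 0.0045, so 3-SE bands of
≈ 0.013); the burn-in of 100 generations is safely past the transients of
the coefficient-½ recursions, which equilibrate within tens of
generations. Fixture presets cover non-overlapping (p=0), overlapping
(p=1), deterministic and high-noise (20% CV) regimes at 2,000 generations.
The threshold simulator uses shorter runs (a few thousand generations)
because of its fine time grid. Ranking experiments use 5,000-generation
lineages, where the generating model's quadruple is separated from the
alternative by ~0.1–0.2 in I.

## What the synthetic data do and do not show

The generators realize the models' own assumptions: Gaussian parameter
noise, stationary growth, symmetric division (unless septum noise is
enabled), no measurement error, no sister-cell or environmental
correlations, no nutrient dependence of the means. Passing oracle tests
shows the simulators and formulas are mutually consistent and that the
diagnostic suite separates the models *under those assumptions*; it does
not show which model real cells follow — segmentation noise, finite
lineage lengths and non-stationarity in real mother-machine data can move
the same correlations materially. Analyses of experimental datasets should
import them via `read_lineage` and treat the closed forms as hypotheses,
not ground truth.

## Known limitations

* No population-tree statistics (single-lineage only), no nutrient growth
  law, no explicit chromosome/replisome dynamics, no image-derived error
  model.
* CCCP closed forms degrade in strongly mixed regimes (above).
* The sHC cross-correlation mode draws per-generation triples jointly but
  does not combine with mother-daughter AR coupling.
* The I-value carries no significance test or null distribution; it is a
  descriptive determinant.
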