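# Methods

## The dynamic network model

The model tracks the activities $x_i(t) \ge 0$ of six nodes — AR (i=1),
PI3K (2), PTEN (3), p65 NF-κB (4), IκB (5), c-Myc (6) — through

$$\dot x_i = J_i - d_i x_i + \sum_j A_{ij} x_j + \sigma_i .$$

The dynamics are linear except for the positivity boundary: after every
integration step each activity is clamped at zero, where it stays until
its net production turns positive again. Default parameters:

* $J = [1.5,\; 2,\; -0.1,\; 2,\; -0.1,\; 0.8]$ — base production; the
  small negative entries for PTEN and IκB mean these nodes have no
  activity unless induced (PTEN by PI3K, IκB by p65).
* $d_i = 1$ for all $i$ — all proteins are assumed to degrade at
  approximately the same rate; time is therefore measured in units of the
  common protein half-life scale, and activities are in arbitrary units.
* $A$ (row = target, column = source):

  |       | AR   | PI3K | PTEN | p65  | IκB  | cMyc |
  |-------|------|------|------|------|------|------|
  | AR    | 0    | −1   | 0    | 0.5  | 0    | 0.7  |
  | PI3K  | 0    | 0    | −2   | 1    | 0    | −0.5 |
  | PTEN  | 0    | 2    | 0    | 0    | 0    | 0    |
  | p65   | −0.9 | 1.5  | 0    | 0    | −3   | 0.5  |
  | IκB   | 0    | 0    | 0    | 3    | 0    | 0    |
  | cMyc  | 0    | 0.5  | 0    | 1    | 0    | 0    |

  This encodes the experimentally motivated circuit: AR represses p65
  while p65 (and c-Myc) induce AR; PTEN inhibits PI3K which induces PTEN,
  p65 and c-Myc; and the strong p65 ↔ IκB pair (±3) forms the NF-κB
  negative feedback loop, which is what produces the damped oscillations
  visible after perturbations.

The row/column convention of $A$ is not self-evident from a typeset
matrix alone; the adopted reading (row = target) is the one that
reproduces every stated biological link with its stated sign, and is
frozen as such.

**Fixed point and stability.** Setting the rate and noise to zero gives
$(\mathrm{diag}(d) - A)\,x^* = J$, solved directly (`numpy.linalg.solve`);
systems with condition number above $10^{12}$ are rejected as having no
numerically meaningful unique fixed point. Stability is classified from
the spectrum of $A - \mathrm{diag}(d)$. For the default parameters the
fixed point is interior (minimum component 0.1590, at p65) so the clamp
is inactive at steady state, and all eigenvalue real parts are negative
(slowest −0.5418), so the linear analysis applies locally without
qualification.

**Scaling.** Activities are in arbitrary units, so the model is defined
up to a per-node rescaling $y_i = \lambda_i x_i$. Substitution shows the
rescaled system is $(J'_i, d'_i, A'_{ij}) = (\lambda_i J_i,\; d_i,\;
\lambda_i A_{ij} \lambda_j^{-1})$: the decay rates are *unchanged* (a
per-node exponential rate cannot be altered by relabelling units), and
diagonal interaction entries are invariant. This trajectory-preserving
form is implemented and verified to $10^{-8}$ against simulation; a form
that also scaled $d$ would not preserve trajectories.

## Integration

A fixed-step explicit (Newton-forward) Euler scheme with $dt = 0.001$ by
default; the clamp `max(0, ·)` is applied after each full step. No
adaptive or implicit scheme is offered — with eigenvalues of order 1 and
$dt = 10^{-3}$ the explicit scheme is deep inside its stability region,
and first-order convergence is verified against the closed-form solution
of a decoupled node (error ratio 2.0 ± 0.2 under halving of $dt$).

**Noise.** $\sigma_i$ is drawn i.i.d. per node *per step* from
$U(-a, +a)$ with $a = 0.01$ by default when enabled. The redraw frequency
is a modelling choice: the forcing is interpreted as fast unresolved
fluctuation, not a slowly varying bias. Note the accumulated effect then
scales like $a\sqrt{dt}$ per unit time, so at $a = 0.01$ the noise is far
too small to flip any of the scenario's directional calls (verified by
test). All noise comes from one `numpy` generator seeded per run; no
global RNG state is touched.

**Perturbations.** A scheduled event multiplies one entry of $J$ at a
stated time; the switch takes effect before the step departing from that
time, and simultaneous events apply in schedule order. Only $J$ is
switchable — the interventions modelled (androgen ablation, NF-κB or
PI3K inhibition) act on production terms.

## The treatment scenario

From $x(0) = [1, 1.2, 1.4, 1.6, 1.8, 2]$ the system relaxes to its fixed
point well before $t = 50$ (baseline window $[40, 50)$ agrees with $x^*$
to $10^{-3}$). Three factor-½ switches follow: $J_1$ at $t=50$ (AR
ablation), $J_4$ at $t=100$ (NF-κB inhibition), $J_2$ at $t=150$ (PI3K
inhibition); the horizon is 200 so each regime spans 50 time units. Each
regime is summarised by its **late window** — the final 40% of its span —
which excludes the post-switch transient; the 40% fraction is a design
choice of this package (the regimes are visually flat well before it).
Directional calls compare late-window means with a 1% relative tolerance
(chosen to sit well above the noise floor at $a = 0.01$ on O(0.1–2)
activities): smaller changes count as "flat" and fail the claim. The
"slightly below baseline" prediction for c-Myc after NF-κB inhibition is
tested as a strict directional inequality only — no magnitude band is
asserted.

## Enrichment statistics

* **Ranking.** Genes are ordered by $\mathrm{sign}(\log_2\mathrm{FC})
  \cdot (-\log_{10} p)$, descending; ties break lexicographically by
  identifier so ranked lists are fully deterministic. $p = 0$ is rejected
  rather than clamped (the synthetic generator floors p-values at the
  smallest positive double).
* **DEG filter.** Strict inequalities: BH-adjusted $p < 0.05$ and
  $|\log_2\mathrm{FC}| > 1$ (one-sided variants available). BH adjustment
  is the standard step-up procedure (via statsmodels), validated against
  hand-computed values.
* **Pre-ranked GSEA.** Weighted Kolmogorov–Smirnov-style running sum:
  increment $|s_i|^w / \sum_{\mathrm{hits}} |s|^w$ at members (default
  $w = 1$), decrement $1/(N-K)$ at non-members; ES is the signed extremum
  (magnitude ties resolve to the positive extremum). The null permutes
  *gene labels* — random same-size member sets — because only a ranked
  list is available at this interface; phenotype permutation would
  require the sample-level data. $p_{\mathrm{perm}} = (1 +
  \#\{|ES_\pi| \ge |ES|\}) / (1 + \#\,\mathrm{sign\text{-}matched}\,\pi)$
  restricted to sign-matched permutations, and $NES = ES /
  \overline{|ES_\pi|}$ over the same set; both conventions follow the
  widely used two-sided normalization. Defaults ($w=1$, $n_{\mathrm{perm}}
  = 1000$) are configurable. Degenerate cases: a set covering the whole
  list raises; a set whose members all carry zero statistic falls back to
  unweighted increments $1/K$; an empty overlap returns an explicit
  empty-overlap result.
* **ORA.** Exact upper-tail hypergeometric $P(X \ge k)$ via
  `scipy.stats.hypergeom.sf`, cross-checked against Monte-Carlo draw
  frequencies.
* **Set activity.** Per-sample mean of per-gene z-scores (sample sd,
  ddof = 1; constant genes contribute 0). This is an *emulation* of
  violin-plot-style per-sample pathway scores — the exact transformation
  used upstream of published figures of this kind (probe collapsing,
  scaling) is generally unstated, so no numerical agreement with any
  published figure is claimed, only the group-level directional behaviour.
* **Rank-sum test.** Two-sided Wilcoxon rank-sum; exact null by full
  enumeration of group assignments (counting $|W - E[W]| \ge$ observed,
  which handles ties through midranks) when both groups have ≤ 8 values,
  otherwise the tie-corrected normal approximation (scipy). The two
  routes agree to |Δp| < 0.02 at n = 8 vs 8.

## Synthetic data

The generator emulates a two-group (e.g. castration vs sham) expression
experiment: gene $g$ in sample $s$ is $N(\mu + \delta_g \cdot [s \in B],
\sigma_b^2)$, i.i.d., with $\delta_g$ the signed planted shift.
Defaults: 2000 genes, 10 samples per group, background $N(8, 1)$
(log2-intensity-like), one planted 50-gene up-set with $\delta = 2$.
Welch's unequal-variance t-test produces the DE table; log2FC is the raw
group-mean difference since values are already log-scale.

Gaussian, equal-variance, independent genes are chosen deliberately: they
make the calibration tests analytically interpretable (null p-values
exactly uniform, type-I fraction ~5%). Real expression data have
heavy tails, gene–gene correlation, mean–variance dependence and probe
structure — none of which is emulated. Passing tests therefore establish
the *correctness and calibration of the statistics*, not robustness to
real-data pathologies.

All generators are deterministic under their seed and touch no global
RNG state.

## Problem sizes

Default test and acceptance runs use: scenario at $dt = 10^{-3}$,
horizon 200; fixed-point/integration cross-check to $t = 500$; scaling
invariance over 20 random vectors at horizon 20; exhaustive ES oracle up
to 12-gene lists with 4-member sets; ORA Monte-Carlo at $10^5$ draws;
null calibration at 5000 genes; and 50 seeded pipeline-recovery runs with
$n_{\mathrm{perm}} = 1000$ against 20 decoy sets. These sizes were chosen
as the smallest at which each statistical criterion has comfortable
resolving power.

## Known limitations

* The interaction weights are set by hand to encode signs and rough
  relative strengths; no fitting to data is provided, and conclusions are
  directional, not quantitative.
* Linear kinetics plus a clamp cannot express saturation (Hill) effects;
  strong perturbations that drive nodes to the boundary leave the linear
  stability analysis only locally valid.
* Gene identifiers are opaque case-sensitive strings; no probe/symbol
  mapping, normalization or batch correction is included.
* Gene-permutation GSEA (the only option for a pre-ranked list) is known
  to be anti-conservative relative to phenotype permutation when genes
  are correlated; on the independent-gene synthetic data this does not
  arise, and the null calibration tests confirm super-uniformity there.
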