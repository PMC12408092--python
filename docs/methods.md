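# Methods

## Life cycle and reproduction model

The population holds exactly N diploid individuals at every generation
(Wright–Fisher).  Each generation is either clonal or sexual, set by a
schedule shared by the whole population:

* **Clonal (mitotic) generation.**  Each of the N offspring samples one
  parent with probability proportional to fitness and copies both of its
  haplotypes intact.  There is no mitotic recombination or gene
  conversion, so the two haplotype lineages within an individual can
  never coalesce along a clonal chain, and a lineage keeps its homolog
  identity through the whole clonal epoch.
* **Sexual (meiotic) generation.**  Each offspring unites two gametes
  from two parents drawn independently with probability proportional to
  fitness (with replacement, so self-pairing occurs with probability
  1/N; explicit selfing biology is out of scope).  A gamete is built per
  chromosome by choosing the starting homolog with probability ½ and
  switching homologs between consecutive tracked sites with the Haldane
  (no-interference) recombination fraction r_i = ½(1 − e^(−2 d_i)),
  d_i = gap·ρ_α.

Selection acts at every cell division: fitnesses are 1, 1+hs, 1+s for
0/1/2 copies of the beneficial allele.  Fixation means every individual
is homozygous for the beneficial allele, which is impossible without at
least one meiosis when the sweep starts from a single heterozygote.

**Meiosis schedules.**  With meiotic frequency α, `fixed` mode puts a
sexual generation every round(1/α) generations, the first one a full
interval after schedule start; `gaussian` mode draws each interval from
Normal(1/α, (1/(10α))²), rounds to the nearest integer and floors at 1
(the rounding rule is our choice; it changes the realized SD by the
rounding variance 1/12).  Conditioned sweep runs use a burn-in that is a
multiple of the interval, so the beneficial mutation (one copy, random
haplotype of a random individual) enters immediately after a sexual
generation; an arbitrary phase can be had by choosing `burn_in` freely.

**Conditioning on fixation.**  If the mutation is lost, or has not
fixed within `max_sweep_generations` (default 10,000), the sweep phase
restarts from the post-burn-in state with fresh randomness.  Because
the selected-locus dynamics are independent of the neutral burn-in
state, this is statistically equivalent for sweep-conditional
quantities to rerunning the whole simulation, at a fraction of the
cost; `strict_rerun=True` reruns the burn-in as well.

## Genome discretization

A chromosome of L basepairs is represented by its tracked neutral loci,
one per diversity window (default 50 loci / 20 kb windows per Mb, at
window centres), plus the selected site.  Within-window recombination
is not modelled; each tracked locus stands for its window.  Escape from
hitchhiking is approximately linear in r over a window, and r is
approximately linear in distance at window scale, so the window average
of π is well approximated by the window-centre value; the error is
second order in ρ_α·window_length.  A second chromosome assorts
independently (r = ½ per meiosis) and carries only neutral loci
(default 10).

## Genealogies and diversity

Every reproduction event records, per offspring haplotype and tracked
locus, the parental haplotype slot it was copied from.  The genealogy
of a sample (default 100 individuals = 200 haplotypes, drawn without
replacement at fixation; all individuals if N < 100) is obtained by
backward lineage tracing through this record: lineages that land on the
same parental slot coalesce.  The result is born simplified — every
internal node is a coalescence and all pairwise TMRCAs are exact — and
is equivalent to tree-sequence recording followed by simplification
(one test cross-checks the π estimator against tskit's site-mode
diversity on an identical genealogy).

Lineages that have not coalesced by the start of the recorded history
are joined by a neutral Kingman coalescent with pairwise rate 1/(2N)
per generation ("root grafting", the recapitation step).  Grafting is
panmictic with size N even when α < 1: the α-dependent excess of
within-individual coalescence times is generated by the forward
burn-in, not by the deep history.

Neutral mutations are overlaid as a Poisson process: each branch
receives Poisson(μ·window_length·branch_length) mutations (infinite
sites within a window; back mutation is negligible since μL per
generation ≪ 1), and window diversity is

    π = Σ_v x_v (2n − x_v) / [C(2n, 2) · L],

the mean pairwise difference per site among the 2n sampled haplotypes.
A variance-reduced branch-mode alternative, 2μ·(mean pairwise TMRCA),
is provided; site mode is the default because the reported statistic is
overlay-based.  The baseline π₀ is the mean chromosome-2 π of α = 1
sweep-free runs at the same N and μ; where a sweep-free run supplies
the baseline, all windows are averaged (they are exchangeable) to
reduce the noise of the normalisation.

## Analytical predictions

* **Haldane mapping**: r = ½(1 − e^(−2d)) with exact inverse.
* **Fixation time (semidominant)**: t_s = (4/s)[ln(2N_e s) + 0.5772],
  valid for 2N_e s ≫ 1.
* **Heterozygote-phase duration**: before any meiosis the beneficial
  allele exists only in heterozygotes, which compete clonally with a
  haploid-like advantage hs, giving
  t_s1 = (2/hs)[ln(2N_e hs) + 0.5772]; the homozygote phase after the
  meiosis has the mirrored form with advantage (1−h)s.  The expected
  number of meioses during the heterozygote sweep is α·t_s1.
* **α-modified selection recursion**:
  Δq = s·q(1−q)[α(h + (1−2h)q) + (1−α)·2h], which reduces to the
  standard diploid recursion at α = 1 and to the haploid form with
  coefficient 2hs at α = 0, interpolating linearly in α.  This
  mean-field form treats the population as partially sexual at all
  times and is known to be crude when α is small: the true rare-sex
  sweep is two sequential clonal phases (durations ~t_s1 + t_s2), not
  one logistic of roughly half that length.
* **Standard rescaled sweep prediction.**  The post-sweep π/π₀ at a
  site with per-meiosis recombination fraction r is computed by the
  classical trajectory-integral structured-coalescent approximation
  with the net rate r·α: a lineage fails to escape the sweep with
  probability P = exp(−rα·Σ_t(1−q(t))) along the deterministic
  trajectory, and

      π/π₀ = 1 − P²(1 − t_fix/(2N_e)),

  the last factor being mutational recovery over the sweep duration.
  The trajectory is iterated from the conditioning-corrected endpoints
  q₀ = 1/(4N_e h s e^γ) and 1 − 1/(4N_e (1−h) s e^γ), which make the
  deterministic duration match the closed-form conditional fixation
  time (414.6 at N_e = 1000, s = 0.05, h = ½).  The star-like escape
  accounting ignores pair coalescence during the sweep and so
  overestimates escape close to the selected site; it is used here as
  the standard-theory reference, which is accurate at α = 1 on window
  scales and systematically underestimates diversity at small α.
* **Single-meiosis prediction** (regime α·t_s1 ≲ 1).  Every
  heterozygote is a clonal copy of the original mutant, carrying
  neutral allele *a* on the beneficial haplotype and *b* on the
  homolog.  The lone meiosis builds homozygotes whose two neutral
  copies are *a* with probability 1−r and *b* with probability r per
  gamete; after the homozygotes replace everything, the neutral site
  carries exactly two allelic lineages at frequencies 1−r and r, so
  heterozygosity is 2r(1−r)·π₀ — at most 0.5·π₀ at r = ½, independent
  of N_e (a deterministic, not stochastic, control of diversity).
  Mutational recovery over the two clonal phases adds
  [(1−r)² + r²]·(t_s1 + t_s2)/(2N_e) to the ratio (identical-by-descent
  pairs coalesce near the sweep origin; π₀ = 4N_e μ cancels the μ).
  With μ = 0 the recovery term is dropped, recovering the bare 2r(1−r).
* **Parameter rescaling to natural populations**: in the standard
  regime (α·t_s1 ≫ 1) s and r are multiplied by N_s/N_n with α
  unchanged; in the rare-meiosis regime r is left alone (2r(1−r) is
  scale-free) and α is multiplied by N_s/N_n.

## Desk-scale study conditions

Full-scale runs (N = 1000, two 1 Mb chromosomes, 500 replicates) are
cluster-sized.  Tests and the acceptance script run the same
configurations under the rescaling f < 1: N → fN, burn-in and run
length → f×, s → s/f, α → α/f, μ → μ/f, ρ_α unchanged (when α would
exceed 1 the remainder moves onto ρ_α).  This preserves 4Nμ, 2Ns,
2Nαr and α·t_s1 — the dimensionless quantities controlling every
ratio examined.  The footprint runs use f = 1/5 (N = 200, s = 0.25,
α = 0.05, μ = 5×10⁻⁸) with 80–100 sweep replicates and a 40-replicate
sweep-free baseline; neutral-equilibrium checks use f = 1/10 with 70
replicates; fixation-time checks need no genealogy and run at full
parameters (N = 1000, 600–800 fixing replicates) with the
genotype-count simulator, which is distribution-matched against the
full simulator by a KS test in the suite.  Replicate counts trade
Monte-Carlo error (SE of a window ratio ≈ 3 percentage points at 80
replicates) against desk-scale runtime; tolerances in the tests are
stated in SE units of the runs themselves.

## What the generator emulates — and what it does not

The simulator generates its own data; there is no external input.  It
captures drift, hitchhiking, the discreteness of rare meioses, the
slower within-individual coalescence under clonality (the ~2–3% neutral
π excess at small α), and recovery of diversity during sweeps.  It does
not model mitotic recombination or gene conversion, selfing or
intratetrad mating, haploid life phases, background selection,
recurrent or overlapping sweeps, demography, or crossover interference.
Passing tests therefore speak to the idealized two-chromosome,
single-sweep, outcrossing model — not to the full complexity of real
yeast populations.

## Numerical choices and degenerate inputs

* Euler–Mascheroni constant truncated to 0.5772, matching the printed
  closed forms.
* Gaussian intervals rounded to nearest integer, floored at 1; fixed
  intervals use round(1/α).
* Genotype-count simulation uses exact multinomial sampling over the
  three genotypes (clonal: fitness-weighted parent probabilities;
  sexual: Hardy–Weinberg probabilities from the fitness-weighted gamete
  frequency).
* Single-replicate summaries report SD = 0 with an explicit
  `sd_defined=False` flag; π₀ ≤ 0, μ < 0, r = ½ inversion, out-of-range
  q, genotypes or α all raise immediately.
* Per-replicate RNG streams derive from SeedSequence((master_seed,
  replicate_id)): replicates are independent, individually re-runnable,
  and bitwise reproducible.
* Dunn's post hoc test is implemented in-package (rank z-statistics
  with tie correction, Holm adjustment), as no installed library
  provides it.

## Known limitations

The standard-theory function is a deliberate reference implementation
of the crude rescaled approximation, including its documented failure
at small α.  The single-meiosis recovery term uses the closed-form
phase durations rather than integrating the stochastic phase lengths;
in the α·t_s1 ≈ 1 transition zone neither analytical model is
accurate.  The window-centre discretization slightly overstates π at
windows whose r(d) profile is strongly concave (relevant only when
ρ_α·window_length is large).  At the window spanning the selected site
the simulator's post-sweep diversity under rare sex (α = 0.01
configuration) runs a few percentage points above the obligate-sex
value, consistent with the 2r(1−r) escape core evaluated at the
window-centre recombination fraction; the obligate-sex value matches
the ~22% figure commonly quoted for this configuration.
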