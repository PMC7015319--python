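# Methods

## Model

`ribosim` treats translation in one prokaryotic cell as a continuous-time
Markov jump process over integer copy numbers. The state is: every free
molecular pool (ribosomal subunits, Ef-Tu in its GTP/GDP/Ts-bound forms,
free Ef-Ts, Ef-G in GTP/GDP/apo forms, RF1, RF2, RF3 in GTP/GDP forms,
RRF, and each elongator tRNA species as deacylated, charged, or in free
ternary complex), plus every bound ribosome with its phase, P-site codon
index and bound ligands, on every mRNA copy.

The ribosome walks an ordered sub-step machine:

* initiation — 30S:PIC association with an unoccluded start region
  (second order), 50S joining (second order), first-order maturation to
  an elongation-competent 70S. The 30S pre-initiation complex is a
  pre-lumped pool: IF1/IF2/IF3 and the initiator fMet-tRNA travel inside
  it and are returned with it at recycling. The initiator is therefore
  not an elongator species and does not enter the tRNA conservation
  laws.
* elongation, per codon — ternary-complex delivery (second order,
  species-resolved: only TCs cognate to the A-site codon can bind),
  GTPase activation/hydrolysis, accommodation (with an optional
  proofreading rejection branch, default rate 0), peptidyl transfer,
  Ef-G:GTP binding (second order), translocation (gated by the footprint
  rule; releases the E-site tRNA to the deacylated pool), and release of
  Ef-Tu:GDP + Ef-G:GDP.
* termination/recycling — class-1 RF binding (RF1 reads UAG, RF2 reads
  UGA, both read UAA — the standard biochemistry), RF3:GTP binding,
  peptide release (returns the class-1 factor, produces RF3:GDP), RRF
  binding, and subunit splitting (frees the 50S, returns a 30S:PIC,
  releases the deacylated P-site tRNA).

Pool-level cycles close the loops: lumped aminoacylation (one effective
first-order reaction per tRNA species — the synthetase, amino-acid and
ATP dependences are folded into the rate, since detailed kinetics are
known for only a couple of synthetases), ternary-complex formation
(charged tRNA + Ef-Tu:GTP, second order) with an optional dissociation
back-reaction (default 0), the Ef-Tu:GDP + Ts association /
exchange-and-release cycle, and effective first-order GDP→GTP turnover
on Ef-G and RF3 (GTP concentration folded in). Amino acids and
nucleotide phosphates are held constant; mRNAs are neither made nor
degraded; all factor totals are constant — the quasi-steady-state
assumptions appropriate for exponential growth.

Stop-codon read-through, premature termination and misincorporation are
hooks: drop-off and accommodation rejection are implemented branches
with default rate 0; a nonzero read-through rate is rejected at
configuration time rather than silently ignored.

## Footprint geometry

A bound ribosome occupies 8 codons 5' of its P site and 6 codons 3' of
it (15 codons, 45 nt). Between two ribosomes at P sites `p < q` a
forward move of the upstream one is blocked iff `q − p < 15`; loading a
new 30S:PIC (which sits at P site 1) requires the 5'-most ribosome to
have `p ≥ 16`. The boundary is half-open by convention: a follower
exactly 15 codons behind its leader may still translocate, so the
instantaneous separation can transiently touch 14 while every *move* is
taken at ≥ 15. The run-time invariant checked in tests is therefore
separation ≥ 14 always, with the ≥ 15 gate enforced at each firing.

## Exact simulation with logarithmic event selection

Events are drawn by the exact SSA: waiting times are exponential in the
total propensity Φ, and the reaction is selected proportionally to its
propensity. Per-mRNA partial sums φᵢ live in a binary tree whose root is
Φ; selection descends the tree comparing r·Φ with left-subtree sums and
an update re-traces one root-to-leaf path, giving O(log₂N) work per
event. Internal nodes are always recomputed as the exact sum of their
children, so the node-sum invariant holds to float associativity rather
than accumulated drift; the engine additionally audits root-vs-leaf-sum
agreement every 10³ events.

Pool-coupled reactions are the design crux: a ternary-complex formation
event changes the TC-delivery propensity of *every* ribosome waiting on
that species, which naive per-mRNA caching would make O(N) per event.
The engine instead keeps only the pool-independent first-order reactions
in the per-mRNA leaves and aggregates every bimolecular ribosome–pool
association into a species-level channel on the dedicated global leaf:
channel propensity = per-pair factor × pool count × number of waiting
complexes, with waiter sets supporting O(1) add/remove/uniform-sample.
Because all waiting complexes of a class have identical per-pair
propensity, drawing the target uniformly on firing is *exactly*
equivalent to enumerating each waiter separately — no approximation, no
rejection step, and O(1) channel refreshes per event. A reference
direct-method engine (full re-enumeration + linear scan each step,
sharing only the reaction definitions and the firing code) provides the
independent statistical oracle; the equivalence test compares
per-(reaction, species, mRNA) firing counts (χ²) and waiting-time
distributions (KS) over 10⁵ events.

Within-mRNA and within-channel ties are broken by list order, which is
statistically immaterial (all orderings realise the same distribution).
All randomness comes from one seeded PCG64 stream; identical seed and
inputs give bit-identical trajectories. When Φ reaches zero the run
ends with a deadlock report listing the waiting complexes and exhausted
pools.

## Rates and pools

Default rate constants are round, literature-scale values: associations
near the diffusion limit (10⁷–10⁸ M⁻¹s⁻¹, converted by k/(N_A·v) with
default volume v = 1.0 μm³), catalytic sub-steps of 60–250 s⁻¹ chosen so
the per-codon budget reproduces in-vivo elongation (~18 aa/s at
reference concentrations), termination/recycling fast enough that a
maximally initiated mRNA does not jam, and an effective aminoacylation
turnover of 25 s⁻¹ per deacylated tRNA. Every entry is overridable from
a TSV; the catalogue validates completeness and refuses unknown names.

Factor and tRNA totals scale linearly with the ribosome count through a
per-ribosome ratio table (defaults: Ef-Tu 8, Ef-Ts 1, Ef-G 1, RF1 0.15,
RF2 0.25, RF3 0.2, RRF 0.6, tRNA 9.5 per ribosome) so a cell is fully
specified by its ribosome count, volume and transcriptome. Perturbation
arms (e.g. ×2 Ef-Tu, +50% Ef-Tu/Ef-Ts, ×2 everything) are expressed as
multipliers on top of the ratios. The packaged tRNA profile is a
theoretical E. coli K12 abundance table matched to ORF codon usage,
tabulated at three growth rates; the tRNA→codon decode map is the
standard 42-species wobble assignment, shipped as an editable TSV.

## Scaled-down cells

The reference cell has 15,000 ribosomes in 1.0 μm³ (the 50S count
implied by the spacing identity for a 1.2 Mnt transcriptome at ~86%
activity and ~93 nt spacing). Desk-scale experiments use miniature
cells of ~50–100 ribosomes whose volume shrinks by the same factor, so
every concentration — and hence every per-pair bimolecular rate times
pool size — is unchanged; the miniature is a faithful, noisier replica
rather than a diluted cell. Transcriptomes are sized at the reference
80 nt per ribosome with short genes (log-normal, mean 50 aa) so that
~40–50 mRNAs fit the nucleotide budget. Growth-rate-like comparisons
keep the volume of the larger cell while reducing ribosomes and factors
together, which lowers all concentrations exactly as a slower-growing
cell does.

The emergent-property arms use: a matched transcriptome (codon usage =
equal-split usage of the tRNA profile); a mismatched rebuild of the
*same* genes and copy numbers whose usage derives from a power-tilted
profile (weight^0.5), compressing the abundance spread and overloading
the rarest species a few-fold — the magnitude of divergence seen
between genomic codon bias and measured tRNA abundances; and an
instant-recycle arm in which aminoacylation, TC formation and the Ef-Ts
cycle are bypassed and ejected tRNAs return to free TC immediately (the
assumption of simpler models). Arm runs last 150 simulated seconds with
a 1 s observer cadence; these sizes were chosen as the package's
standard desk-scale conditions.

## Observables

* `C_p` — per-protein amino acids incorporated divided by
  elongation-phase duration (initiation and termination excluded;
  switchable to full dwell time), averaged over completions in the
  quasi-steady tail (default: discard the first half of the run), with
  a trailing-window running average available.
* State fractions — every 50S equivalent is free, initiating (post-50S
  joining), elongating or terminating, so %I+%E+%T+%50S = 100 exactly;
  the 30S side is tracked separately (a loading PIC holds no 50S).
  `beta_r = 100 − %50S`.
* Stalling — an elongating ribosome is stalled when its A site awaits a
  TC and every cognate species has zero free TC (starvation), or when
  it is translocation-ready but footprint-blocked. %S is reported both
  as a fraction of elongating ribosomes (default) and of all engaged
  ribosomes, since both accountings are in use.
* Free-TC ratios — per species, time-averaged free-TC copies over total
  copies in the last 100 s window (clipped to the final half of shorter
  runs).
* Decode statistics — each peptidyl transfer logs its codon, tRNA,
  A-site waiting time and a starvation flag set if the wait ever saw
  all cognate TC pools empty; per-codon means, counts and stall
  frequencies summarise the log. The ledger identity (decode events =
  completed-protein bonds + in-flight bonds) is exact.
* Spacing — `d_r = N_nt/(β_r·N_50)` (β_r as a fraction) and `ρ = 1/d_r`,
  warning when d_r falls below the 45 nt footprint.
* Replicates — the summary tool aggregates multiple trajectories to
  mean ± SD.

## Synthetic data and what the tests show

The toy generator produces micro-cells (few genes, reduced codon
alphabet, 1–2 tRNA species, ~5 ribosomes) with round rates and one
deliberately rate-limiting step, making analytic limits tight: the
serial-pipeline elongation rate equals the harmonic sum of sub-step
rates, extinction of a pure-death pool has closed-form mean, and the
charged⇄TC two-state toy settles at a/(a+b). Toy cells carry a small
TC-dissociation rate (2 s⁻¹) because with only a handful of Ef-Tu
copies the system is otherwise non-ergodic — every Ef-Tu can end up
trapped in ternary complexes of the species the next codon does not
need. Synthetic gene-length lists are log-normal stand-ins for a
proteome length table.

What passing tests show: the sampler is exact (engine equivalence,
waiting-time law, analytic limits), the bookkeeping is exact
(conservation, footprint exclusion, propensity-cache audits), and the
qualitative physiology emerges under realistic concentrations. What
they do not show: quantitative agreement with any particular organism's
measured rates — sequences are i.i.d. codon draws, not real mRNAs;
initiation is maximal on every mRNA (no 5'-UTR structure); and the
miniature cells amplify stochastic fluctuations relative to a full-size
cell.

## Numerical choices and limitations

* Second-order propensities use k·n₁·n₂/(N_A·v); volume enters nowhere
  else.
* Channel values and tree nodes are refreshed from current counts (not
  deltas); the global leaf is re-summed every event from ~60 channel
  values, and audits every 10³ events bound any residual float drift at
  1e-9 relative.
* Copy numbers of zero are resampled away by default (a selected gene
  is expressed); the raw mixture distributions are available by
  switching truncation off.
* The codon-usage matching solver returns the minimum-norm NNLS
  solution; wobble cross-recognition makes the system rank-deficient,
  so the returned profile is *one* feasible solution and is flagged as
  degenerate. Continuous abundances round-trip to 1e-6; integer
  rounding (largest remainder) trades that for exact totals.
* Single-codon ORFs terminate without decode events and are excluded
  from C_p.
* Full-scale cells (T07/T10/T25-shaped presets, 7,000–64,000 ribosomes,
  0.5–5 Mnt transcriptomes) are expressible as configs and run
  overnight rather than in the test suite; desk-scale results use the
  miniature cells described above.
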