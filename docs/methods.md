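# Methods

## Model

Translation is coarse-grained into a cycle of three sequential steps —
initiation, elongation (⟨ℓ⟩ codon additions), termination — each catalyzed
by dedicated translation factors. In steady-state exponential growth every
intermediate carries the same ribosome flux, so the growth rate is the
active-ribosome fraction divided by the cycle time (rescaled by
⟨ℓ⟩/ℓ_ribo), and the share of ribosomes resident at a step equals the
share of cycle time spent there. Factor levels enter through mass-action
waiting times: in the binding-limited regime each sub-reaction costs the
diffusive search time 1/(k_on·φ). The proteome constraint makes factor
expression a zero-sum trade against ribosomes inside a fixed translation
sector φ_tl.

Assumptions inherited from this coarse-graining:

- **One effective codon class.** All tRNA isoacceptors, synthetases and
  ternary complexes are lumped into single effective species; reactions
  that were codon-specific keep a 1/n_aa rate dilution (n_aa = 20). The
  sharpness of the EF-Tu/aaRS regime separation is a direct consequence of
  this small parameter.
- **No mRNA-resolved ribosome traffic.** Queuing at stop codons is
  represented only by a pluggable multiplicative hook (default 1, the
  fast-termination regime); no TASEP-style modelling.
- **Effective rate constants.** Off-rates and proofreading are absorbed
  into effective k_on values; reactive-surface geometry is assumed equal
  across reactions so rates can be scaled by diffusion coefficients.
- **Fixed sector and budgets.** φ_tl, the inactive-ribosome fraction, and
  the total tRNA budget are measured inputs, not optimization variables.

The optimality condition (∂λ/∂φ_i)* = 0 decouples at the optimum: each
factor solves its own step, connected to the rest only through λ*. For a
wait a/(k_on·φ) used u times per protein the optimum is
φ* = √(a·u·ℓ_ribo·λ*/(⟨ℓ⟩·k_on)), equivalently the equipartition point
where the free factor pool equals the ribosome pool waiting for it. The
self-consistent λ* is found by damped fixed-point iteration (damping 0.5,
relative tolerance 10⁻¹², cap 500 iterations; typical convergence in
15–40 iterations), alternating between evaluating all φ_i*(λ) and closing
the allocation through the growth law.

### EF-Tu / aaRS coupling

The ternary-complex level solves tRNA conservation across free
charged/uncharged tRNA, TC, and ribosome-held tRNA (elongating ribosomes
hold ~2; ribosomes with occupied A sites are lumped as 2λ/k_el_max). The
growth rate enters as an exact saturation curve λ = a·φ_TC/(K_TC + φ_TC),
with a and K_TC computed from the full cycle rather than fitted — K_TC is
also reported for scaling the landscape panels. The expression plane
splits into an EF-Tu-limited regime (φ_TC ≈ φ_Tu) and a charging-limited
regime, separated by the transition line
Δ_tRNA(φ̄_Tu) = n_aa·λ/(k_on^aaRS·φ̄_aaRS), where Δ_tRNA is the budget left
after ribosome- and TC-held tRNAs. The optimum is the intersection of the
line with the EF-Tu-only optimum; the aaRS optimum
φ_aaRS* = n_aa·λ*/(k_on^aaRS·Δ_tRNA*) is therefore linear in λ*/Δ* and is
the one factor whose stoichiometry shifts with growth rate.

Two boundary facts worth noting, because naive intuition gets them wrong:
as φ_TC → 0 the growth rate vanishes proportionally, so the conservation
residual tends to the finite surplus ψ_tRNA − φ_act/ℓ_ribo rather than
diverging; the divergence is at the other end (φ_Tu^GTP → 0⁺). For the
same reason the excess budget at vanishing EF-Tu tends to
ψ_tRNA − φ_act/ℓ_ribo, slightly below the full budget.

Under the default (tight) tRNA budget the joint 2D optimum slides a few
percent along the transition line relative to the factored analytic pair —
the aaRS optimum is the model's most budget-sensitive quantity. The
brute-force verification therefore checks each factor's own optimality
condition (1D maximization at the partner's optimum, agreement within 1%)
and separately that the joint 2D argmax satisfies the transition-line
equation (within ~10⁻³ relative).

### Initiation reconstruction

The initiation optimum is assembled from the structure of the ordered 30S
pre-initiation scheme: direct binding waits with structural prefactors
(the IF1 wait inflated by the IF2/IF3 mass riding on the 30S complex,
1 + (ℓ_IF2+ℓ_IF3)/ℓ_ribo; a 3/4 prefactor on IF2 and IF3), additive
"other" pools for each factor sequestered during IF1 binding and 50S
joining (one square-root term per grouped table entry), and catalytic
terms for mRNA loading and subunit joining. The coarse kinetic τ_ini
implements the binding waits and, when a free-50S level is supplied, the
joining wait; the sequestration pools in the optimal abundances are a
solution-level reconstruction and do not feed back into τ_ini. This
residual asymmetry is confined to the initiation factors and does not
affect the allocation-closure or growth-law invariants, which hold at the
fixed point by construction.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| P | 2.6×10⁶ | µM | in-protein amino-acid concentration, ~growth-rate independent |
| ⟨ℓ⟩ | 200 | codons | expression-weighted mean protein length (computable from any expression table via `avg_protein_length`) |
| ℓ_ribo | 7300 | aa | ribosomal protein content per ribosome |
| n_aa | 20 | – | coarse-grained codon/amino-acid classes |
| φ_tl | 0.145 | – | translation sector sized so the binding-limited optimum lands in the fast-growth regime (doubling ≈ 19 min) |
| φ_ribo^inact | 0.01 | – | ~5% of the ribosome pool inactive at fast growth |
| ψ_tRNA | 2×10⁻⁴ | – | [tRNA_tot]/P ≈ 520 µM total tRNA, a fast-growth estimate; deliberately *tight* — the budget barely covers ribosome- and EF-Tu-held tRNAs, which is the physiological situation |
| k_el^max | 22 | s⁻¹ | maximal codon elongation rate (catalytic ceiling) |
| (f_UAA, f_UAG, f_UGA) | (0.6, 0.1, 0.3) | – | stop-codon usage; organism-specific, override for precise work. δ = 2·f_UAG·f_UGA corrects the combined RF1+RF2 level for their split stop-codon specificity |
| k̂_on^TC | 6.4 | µM⁻¹s⁻¹ | measured ternary-complex/ribosome association; reference for all diffusion-scaled estimates |

Per-factor lengths are canonical *E. coli* gene products; the effective
aaRS length (650 aa) is the mean over the twenty synthetases. Measured
in vivo diffusion coefficients anchor the table (EF-Tu 2.6 µm²/s, ribosome
0.04, TC 2.2, 50S 0.3, free tRNA 8.0); everything else is estimated by
cube-root length scaling from the EF-Tu anchor and pair-wise diffusion
scaling of k̂_on (ribosome partner assumed unless the reaction dictates
otherwise — tRNA for aaRS and EF-Tu, EF-Tu for EF-Ts). A user-supplied
measured k̂_on always overrides the estimate (logged).

Two kinetic regimes are exposed everywhere as `mode`: `binding_limited`
(k_cat → ∞, the default, used for all headline predictions) and
`catalytic`, which adds 1/k_cat residences to transit times and sequesters
the fraction u·λ·ℓ/( ⟨ℓ⟩·k_cat) of each factor at its chemical step (u =
uses per protein); binding waits then run on free fractions. Catalytic
rates are not bundled — in vitro values are sparse and often inconsistent
with in vivo flux — so catalytic mode requires user k_cat values.

## Observed-data fixture

The bundled `observed_synthesis_fractions_synthetic.tsv` is **synthetic**
(and labelled so in its header): three species with fast-growth-magnitude
synthesis fractions and EF-Tu/EF-G ratios fixed to the reported species
values (3.9 / 2.7 / 3.3). It emulates the structure of
ribosome-profiling-derived synthesis-fraction tables — enough to exercise
the comparison code and the printed ratios offline — but it is not
measurement data: absolute per-factor agreement beyond the order of
magnitude, species-level idiosyncrasies, and condition dependence are not
represented. Tests that pass against it demonstrate the comparison
machinery and the model's structural ratios, not empirical validation.

## Numerical choices

- **Conservation solve.** Bracketed Brent root-finding in the logit
  coordinate ln(φ_TC/(φ_Tu − φ_TC)), which conditions both boundaries; the
  residual at the root stays below ~10⁻¹²·ψ_tRNA even when free EF-Tu is a
  10⁻⁹ sliver of the total. Budget infeasibility is detected from the sign
  at the charging-limited end.
- **Divergent times are values, not exceptions.** φ → 0 gives an infinite
  transit time so grid searches can penalize boundaries; allocation- or
  budget-infeasible points map to −∞ growth in the optimizer.
- **Landscapes.** 200×200 logarithmic grids over 10⁻⁴…10⁻¹ in both φ
  axes (about 2 s); infeasible cells carry NaN sentinels plus an explicit
  mask, never silent zeros.
- **Brute-force oracle.** Exhaustive log-grid scan (≤3 free factors;
  coordinate-wise beyond) followed by golden-section refinement per
  coordinate to ~10⁻⁶ relative; fully deterministic, trace retained.
- **Fixed point.** Damping 0.5; convergence on the undamped residual so
  the growth-law closure holds to 10⁻¹⁰ at the reported optimum. Sweeps to
  small sectors start from a low λ to avoid transient allocation overshoot.

## Test-problem sizes

The suite solves the default 9-factor system (fixed point in <50
iterations), one 200×200 landscape, a 5-point sector sweep spanning a
>10-fold λ* range, and oracle searches of 24²–64 points with three
refinement passes — a few seconds in total, chosen to exercise every
regime (both sides of the transition line, the budget plateau, zero-flux
limits) rather than for scale.

## Known limitations

- Appendix-style refinements that are deliberately out of scope: RF3 and
  EF-G's role in termination, non-cognate binding, per-isoacceptor tRNA
  pools, and the explicit queuing-factor closure (hook only).
- The aaRS prediction inherits the full sensitivity of Δ_tRNA* to the
  tRNA budget and should be read as order-of-magnitude.
- Binding-limited mode overestimates absolute growth (no catalytic
  residences), so ribosome-normalized quantities (tRNA/ribosome, EF-Tu per
  ribosome) come out high even when proteome-fraction predictions are
  sensible; the 2 + 4 = 6 minimum tRNA/ribosome diagnostic uses the
  measured EF-Tu:ribosome stoichiometry (~4) rather than the model's.
- The initiation "other"-pool reconstruction (above) is structural, not
  mechanistic; a full pre-initiation kinetic scheme would replace it.
- Diffusion-scaled rate estimates assume equal reactive geometry across
  reactions; the square-root dependence of every optimum keeps the
  predictions within ~√2 even for 2-fold rate errors.
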