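# Methods

## Game, encoding and noise

All components share one convention: joint outcomes are read from the
focal player's perspective and indexed `(CC, CD, DC, DD) = (0, 1, 2, 3)`;
swapping perspective exchanges CD and DC. The default game is the
donation game `(R, S, T, P) = (2, -1, 3, 0)` from benefit `b = 3` and
cost `c = 1`; any `T > R > P > S` matrix may be configured. Execution
noise flips each player's realised move independently with probability
`ε` (default 0.05) *before* payoffs are computed; both players observe
the same post-noise outcome, so pair histories never diverge. Whether
noise should instead corrupt each player's private record is not
determined by the protocol we implement; the shared-outcome reading is
the simplest and keeps the self-recognition machinery well-posed.

## Stationary scores

A match between memory-one strategies `p` and `q` is a Markov chain on
the four outcomes. Long-run means are evaluated through the determinant
identity `⟨f⟩ = D(p, q, f)/D(p, q, 1)` on *effective* (noise-adjusted)
vectors `(1 − 2ε)p + ε`; this is exactly equivalent in distribution to
simulating the noise channel. When `|D(p, q, 1)| < 1e-12` (possible only
at `ε = 0`, e.g. noise-free TFT against itself) the implementation falls
back to averaged power iteration started from mutual cooperation, which
returns the Cesàro limit for periodic chains and the
initial-condition-dependent limit for absorbing ones; callers who need a
unique answer should pass `ε > 0`. A vectorised Monte-Carlo match
simulator provides an independent sampling route used by the tests
(agreement within 3 SE over 10⁶ noisy rounds).

The ZD construction is `p = (1,1,0,0) + φ[χ(Sx − κ) − (Sy − κ)]` with
`Sx = (R,S,T,P)`, `Sy = (R,T,S,P)`. Among the two possible sign
conventions only this one yields valid probability vectors for both
shipped parameter sets (`κ ∈ {R, P}`, `χ = 1/2`, `φ = 0.1`); it enforces
`s_opp − κ = χ(s_self − κ)`, i.e. with `χ = 1/2` the ZD player keeps
twice the opponent's surplus over `κ` — extortionate for `κ = P`,
generous ("ZDR") for `κ = R`. A property test pins this relation to
1e-8 against random opponents.

## Frequency-dependent fitness

`mean_score_difference` implements the exact finite-population payoff
difference; note that for "symmetric" types (`S_II = S_GG`, `S_IG =
S_GI`) it equals `(2m − N)(S_II − S_IG)/(N − 1)`, which vanishes only at
the even mixture — the minority type plays more cross-type games per
capita. Tag-based idealisations (ConDef = cooperate with own type,
defect otherwise; ZD_t = own type/ZD) enter the analysis as pairs of
vectors selected by true type labels.

## The information player

Per opponent, IP₀ keeps `(n_AB, m_AB)` counts (outcome AB occurred and
the opponent's next move was observed; of those, next move was C) and
the Beta-posterior means `(m+1)/(n+2)` under a uniform prior. The first
10 rounds per opponent are the infogain phase: choose the own move `A`
minimising `Σ_B p(B|ab)·n_AB`, with exact ties (compared in integer
arithmetic) broken by the MD5 digest of the pair's outcome-history
string — C if the least-significant bit of the digest's final byte is 0.
Each player hashes the history written from its own perspective (own
move then opponent move per round); the rule uses only shared
information, so any IP₀ can predict any other IP₀'s move exactly, and
the digest's last byte is the documented bit source.

Self/non-self classification runs two tracks. During infogain the
binomial tail `P(E ≥ e | n, ε)` of observed mismatches `e` against the
predicted infogain move flags confident non-IP₀ opponents at `α = 0.01`.
In parallel a log-odds ratio `L` accumulates `log p(B|IP₀)/p(B|GP)`
after every round — during infogain the IP₀ model predicts the infogain
move with error `ε`; during groupmax it is a two-state HMM (states:
"it believes I am IP₀ and cooperates" / "it plays its groupmax vector at
me"), switching state with 1% probability per round. The HMM's ALLC
prior at the phase transition is `1/(e^{−L'} + 1)` where `L'` is the
log-odds the opponent would have computed about the focal player from
the realised (post-noise) moves, which both players can see. The
`p(B|GP)` term uses the pooled counts of all confidently identified
non-IP₀ players (plus archived counts of dead ones) once any exists,
else the per-opponent counts, and is noise-adjusted. A newborn player is
assigned the prior `L = log(m̄/N)`; a newborn IP₀ itself knows only that
it is an IP₀, so its own priors start at `log(1/N)`.

The groupmax vector maximises `(N−m̄)/(N−1)·S(q, p̄) − m̄/(N−1)·S(p̄, q)`
over `q ∈ [δ, 1−δ]⁴`, `δ = 1e-3`, where `p̄` is the pooled opponent
estimate re-expressed in the opponent's own frame (a perspective swap of
the focal-indexed posterior means) and `m̄ = 1 + Σ σ(L_i)` the posterior
expected IP₀ count. When no opponent is yet confidently non-IP₀ the
estimate pools over opponents currently classified non-IP₀ (`L ≤ 0`,
past infogain), falling back to the uninformed vector (0.5, 0.5, 0.5,
0.5). The optimiser is projected numerical-gradient ascent (central
differences, adaptive step starting at 0.05, box clamp, objective
tolerance 1e-6, iteration cap) from six starts — ALLC, ALLD, TFT, WSLS,
`p̄` and the previous optimum. Against ZD opponents the objective is
nearly flat in `q` (the enforced score relation removes most of the
dependence), so rows retire after three consecutive sub-tolerance gains;
a grid-scan oracle in the tests confirms optima within 1e-3 of
exhaustive search. Results are memoised with the inputs quantised to
their own statistical resolution: each component of `p̄` is rounded to a
grid no finer than its posterior uncertainty (0.25/0.1/0.05/0.02 for
<10/<50/<500/more observations) and `m̄` to 0.2. Re-optimising for
estimate movements smaller than the estimate's own standard error would
change nothing scientifically and would dominate the runtime of long
simulations.

## Evolutionary engine

Per generation every unordered pair plays one move each, conditioned on
the pair's previous-generation outcome (standard first move — C for all
shipped strategies except ALLD — when the pair has no history), noise is
applied, and fitness is the mean payoff over the `N − 1` games. One
update follows. The *exponential imitation dynamic* is implemented as
the pairwise comparison rule: a uniformly chosen focal player adopts a
uniformly chosen model's strategy with probability `1/(1 + e^{σ(f_focal
− f_model)})`; this is the rule defined in the literature the protocol
cites, its per-event up/down ratio at mixture `m` is exactly
`e^{σ·(S̄_I − S̄_G)}`, and it reproduces the neutral baseline `m₀/N`
exactly. A softmax variant (uniform death, model drawn ∝ `e^{σf}` over
all players) and a Moran-style rule (reproducer drawn ∝ `e^{σf}` —
exponential weighting keeps negative donation-game payoffs admissible —
uniform death) are provided as alternatives. A replaced slot receives a
fresh identity and empty internal state; its pair histories are cleared;
information players archive the counts of a dead opponent they had
confidently classified as non-IP₀ and open a fresh model on the newborn.

Internally, play among memory-one and tag-based players — and among
information players past their infogain window — is vectorised over the
pair matrix; pairs inside an infogain window run the scalar per-opponent
model. A dedicated test drives both paths on the same realised move
stream and checks they produce identical counts, log-odds and HMM
posteriors. At `ε = 0` only genuinely stochastic pair entries consume
randomness, so absorbed pairs (e.g. mutual cooperators locked on CC) are
free. Trajectories are bit-reproducible for a fixed seed and call
sequence.

## Fixation experiments and the metastable mixture

Fixation probabilities are estimated from independent seeded runs
(spawned from a base seed), reported as odds ratios against the neutral
`m₀/N` with exact binomial tail p-values. For most strategy pairs runs
absorb quickly. Some pairs, however, have an interior fitness
equilibrium: ALLC invading the ZD extortioner gains `+0.41` per
generation while rare but loses `−0.32` near fixation, with the analytic
crossing at `m* ≈ 55` of 100. The embedded birth–death chain (ratio
`e^{−σ·diff(m)}`) shows the basin is asymmetric — from the plateau the
chain fixes with probability ≈ 0.985 — but the absorption time exceeds
10⁶ generations, far beyond any sensible budget. `fixation_estimate`
therefore offers fate resolution for fixed-strategy pairs: a run still
unresolved at the generation cap samples its eventual outcome from the
analytic chain's fixation probability at its current invader count,
using the run's own random stream. The cap (600 generations in the
shipped experiment scripts) is chosen to cover the selection-dominated
early phase, where survival is decided; validation against a pure-
simulation estimate on a barrier-free pair (ALLD invading ALLC) agrees
within sampling error. Resolution is unavailable for adaptive players
(IP₀, ConSwitch), whose invasions do not exhibit the metastable plateau
and absorb naturally.

## Simulation scales

The shipped experiment scripts use: 2000 positive + 2000 negative
sequences per ROC curve; 1000 runs for the tag-based-player invasion of
ZDR; 2000 runs (cap 600 generations + analytic fate resolution) for ALLC
invading the extortioner; test-suite replications are further reduced
(e.g. 12–250 runs for the information-player invasions) and asserted
within 3 binomial standard errors at the reduced count. "Perfect"
identification of corner strategies is likewise asserted up to the
binomial resolution of the replicate count: a couple of noise-flip
coincidences per few thousand sequences are expected and observed.

## What the generator does and does not emulate

All inputs are synthetic by construction (the model *is* the data
generator): well-mixed populations, constant size, two types per run,
i.i.d. execution noise, and payoffs fixed over time. Spatial structure,
assortment, more than two concurrent types, perception (as opposed to
execution) noise, and time-varying games are out of scope; passing tests
say nothing about those regimes.

## Known limitations

* The update rule is identified only by name and citation in the
  protocol this package follows; the Fermi pairwise-comparison reading
  is implemented as the default and matches most reported invasion odds
  (e.g. ALLD into ALLC, ALLC into TFT, WSLS into ALLC, TFT into ALLD)
  within sampling error, but the reported odds for invasions of the ZD
  extortioner are about 1.6–1.8× larger than any of the implemented
  one-replacement rules produce; the discrepancy is confined to the
  drift-dominated early-survival phase of that metastable pair.
* IP₀ assumes all non-IP₀ opponents share one strategy when pooling
  counts; with more than two types in play the pooled estimate is a
  mixture.
* `epsilon_assumed` is set to the ambient noise rate; no estimation
  procedure for unknown `ε` is provided.
* The groupmax optimiser is a local method with multi-start and a grid
  cross-check at test scale; pathological opponent estimates could in
  principle hide better optima between grid points.
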