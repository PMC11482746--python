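# Methods

## The problem

A protein with N ionizable residues (Asp, Glu, Cys, Tyr, His, Lys — arginine
stays protonated over the experimental pH range and contributes a fixed +1)
populates 2^N charge microstates, one per assignment of
protonated/deprotonated to every site. Experiments never resolve individual
microstates: potentiometry reports the total degree of protonation, NMR
reports per-residue titration curves. Grouping microstates by their number
of released protons n (equivalently by net charge q = q_max − n) gives N + 1
*mesostates*; the q-canonical observation is that global experiments are
fully described by one standard free energy per mesostate, and site-specific
experiments by one free energy per (site, state, mesostate) triple — a
polynomial number of parameters even though the microstate count is
exponential. This package computes those aggregated free energies *exactly*,
then reattaches the pH dependence analytically.

## Free-energy model

All free energies are standard-state quantities in kcal/mol, relative to the
fully protonated microstate (G ≡ 0); R = 1.9872×10⁻³ kcal/(mol·K), default
T = 298.15 K.

Microstate free energies are assembled along the N-to-C thermodynamic path:
sites release their protons in sequence order, and the cost of deprotonating
site i given the states of the preceding sites is the additive context model

    dE(i | context) = [intrinsic(type_i) + offset(type_i)]
                      + scale(type_i) · Σ_neighbors pair(type_i, type_j, state_j, j−i)

summed over sequence neighbors within a window w on each side (default
w = 5, beyond which neighbor effects are negligible in this model). Because
of the N-to-C path, a right-side neighbor has never yet released its proton
when site i's contribution is added, so right neighbors — and left neighbors
that do not titrate — are always looked up protonated; only left titratable
neighbors within the window carry state dependence. (offset, scale) are
per-type rescaling factors, (0, 1) until calibrated.

## The synthetic context database

Context pair terms would normally come from free-energy simulations; the
package instead generates them from a screened-electrostatics model. A
neighbor carrying charge z in its looked-up state contributes

    pair = −z · A · exp(−|offset| / λ)

to the central site's deprotonation free energy (deprotonation lowers the
central charge by one, so a positive neighbor favors it and a negative
neighbor opposes it — like charges repel in both directions). Defaults:
coupling strength A = 0.6 kcal/mol and decay length λ = 2 residues, chosen
once as a realistic magnitude for solvent-screened nearest-neighbor
interactions in an expanded chain (nearest-neighbor like-charge penalty
≈ 0.36 kcal/mol ≈ 0.27 pH units, with pKa shifts of one to two units when
several charged neighbors accumulate — the size of charge-regulation effects
reported for disordered proteins). Neutral-state neighbors get a small
seeded perturbation (σ = 0.05 kcal/mol, times the same screening factor) so
that context dependence is not artificially restricted to charged species;
the generator is deterministic given (parameters, seed). Intrinsic terms are
RT ln(10)·pKa with model-compound (random-coil pentapeptide) reference pKa
values shipped as an overridable data table.

What the generator does *not* emulate: conformational coupling,
sequence-distant (through-space) interactions, salt dependence, and any
simulation-derived asymmetries between residue pairs. Tests passing under
this model therefore validate the *algorithm* (exactness, scaling,
qualitative charge-regulation trends), not the accuracy of any particular
force field's free energies.

## The streaming engine

The engine never materializes microstates. Walking sites N-to-C it maintains
G[q, c]: the aggregate free energy — under the set-aggregation operator
F(G₁…G_n) = −RT ln Σ exp(−G_i/RT) — of all sequence prefixes with q released
protons ending in trailing context c, where c is the state tuple of the
still-relevant recent sites. At each site every entry branches (keep the
proton: q, c·0; release it: q+1, c·1, plus dE for the new site given c), and
a site's context bit is merged out with F as soon as the next site is more
than w residues away, since it can no longer influence any upcoming dE. The
per-sequence context length m is the largest number of tracked sites ever
needed (m ≤ min(w, N)); the two-state context of the published recursion is
the m = 2 case, and correctness for general m is pinned to the brute-force
oracle rather than to a transcription of those equations. After the last
site, F over surviving contexts gives the N + 1 mesostate free energies.

The site-specific engine carries the identical propagation once per
already-seen position p, split by that position's state s (its (p, s) tables
are inherited from the global aggregate at the step where p branches). The
result is G[p, s, q] for all triples; F-combining s = 0 and s = 1 reproduces
the global table (refinement identity), which holds by construction and is
asserted against enumeration in tests. Impossible combinations (s = 1 with
q = 0, etc.) are +inf and never enter any merge. A design alternative —
collapsing a position's table over contexts once the position leaves the
window — was rejected: future release branches add context-dependent free
energies to *every* carried table, so collapsing early would destroy
exactness. Memory is therefore ~N²·2^m doubles (≈0.4 GB at N = 900, m = 5),
comfortably desk-scale.

### Numerics

Aggregation is max-shift stabilized throughout, with the shift maintained
incrementally: tables are stored as nonnegative scaled weights plus one log
offset per mesostate row (the offset tracks the row's running maximum and is
re-anchored to it every 16 steps). Merges are then plain additions and the
release branch a vector multiply, with no possibility of overflow; underflow
affects only states several hundred RT above their mesostate's dominant
microstates, which contribute nothing at double precision anyway. A weight
of exactly zero encodes an absent combination (+inf free energy). Site
iteration is strictly N-to-C and merge order is fixed, so results are
reproducible run-to-run; randomized tests confirm agreement with explicit
enumeration at ~1e-15 relative, far inside the 1e-9 tolerance asserted.

### Cost

Counting energy additions and F merges: the global scope is O(N²·2^m)
(mesostate index × sites, measured log-log slope ≈ 2 on homopolymers over
N = 25…800) and the site scope one power higher (slope ≈ 3 over N = 25…400,
the range used for the fitted exponent; larger N adds runtime without
changing it), versus 2^N for enumeration (measured log₂ slope ≈ 1 per added
site at N ≤ 20). The headline capability — exact global plus site-specific
tables for a 900-site homopolymer — runs in a few minutes on one core. The
operation counters deliberately exclude bookkeeping: brute force counts one
addition per released site per microstate; the shared-prefix enumerator
counts one per releasing extension (2^N − 1, with 2^(N+1) − 2 total
extension steps); the engine counts branch additions and pairwise merges.

## pH dependence and observables

A mesostate that has released n protons acquires
G(pH) = G_standard − n·RT·ln(10)·pH. (The proton chemical-potential term
must be linear in pH on the free-energy scale; the sign is fixed by
requiring that an isolated site reproduce Henderson–Hasselbalch with
midpoint at its intrinsic pKa.) From the mesostate free energies:
populations p_q by stabilized Boltzmann normalization; mean net charge
⟨q⟩ = Σ p_q·q_net; the global ionization coordinate
f_tot = (⟨q⟩ − q_min)/(q_max − q_min) ∈ [0, 1] (1 = fully protonated);
charge-state variance Var(q); and per-site fractions protonated from the
(p, s, q) table. Apparent pKa is the pH where a site's protonated fraction
crosses ½, refined to 1e-8 pH units on a local cubic interpolant of the
0.05-pH default grid (grid-discretization error ≪ 1e-6 pH); curves with
several crossings report the median crossing and a non-sigmoidal flag,
curves with none report no value.

Two identities worth knowing. ⟨n⟩(pH) is non-decreasing because
d⟨n⟩/dpH = ln(10)·Var(n) ≥ 0 (binding-polynomial derivative). The same
identity means the *signed* midpoint slope of net charge vs pH and the
midpoint charge variance are locked together, d⟨q⟩/dpH = −ln(10)·Var(q):
charge patterning that raises midpoint heterogeneity necessarily steepens
the signed net-charge slope there. The E/K block-variant family shows
exactly this — variance grows, and the slope decreases (grows in magnitude),
monotonically with charge segregation under repulsive like-charge couplings.
Loss of cooperativity shows up instead as the broadening of the individual
acid/base transitions flanking the midpoint plateau.

## Calibration

Per-type (intrinsic offset, electrostatic scale) pairs are fitted to
reference site-specific pKa values by deterministic alternating bounded 1-D
line searches (offset within ±4 kcal/mol of its current value, scale in
[0.2, 5]), sweeping types until the pKa RMSD improves by < 1e-4. An update
is kept only if it strictly improves the objective, so parameters without
influence (e.g. the scale of an isolated site) stay at their defaults.
Targets whose predicted curve never crosses half-protonation in the pH grid
are flagged and excluded with a warning. Self-consistency (targets generated
by the database itself recover the identity transform) and the closed-form
isolated-site offset RT·ln(10)·ΔpKa are asserted in tests.

## Degenerate inputs and edge cases

Records with no ionizable sites have one microstate (G = 0), one mesostate,
and undefined f_tot (returned empty, with a warning). Chain termini can
optionally titrate as pseudo-sites at positions −1 and N_res (off by
default; microstate string labels are undefined for them). Explicit
enumeration refuses N > 20 and points to the streaming engine. A window
override larger than the database window is rejected, as is any in-window
neighbor pair missing from the database (named key in the error).

## Known limitations

Sequence-local context only — no conformational ensemble coupling, no
through-space interactions between sequence-distant residues, no salt or
temperature dependence beyond RT scaling. The shipped database is a
synthetic stand-in: absolute pKa predictions are only as good as its
screened-electrostatics caricature, and the package's validated claims are
the exactness, scaling and trend properties above.
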