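# Methods

## Data model

A finite topological space is stored extensionally: a set of point labels and
the full family of open sets. Validation checks the axioms directly (∅ and
the full set present, pairwise closure under union and intersection — pairwise
suffices on a finite family) and names the first violated axiom with the
witnessing sets. On a finite space the topology is automatically Alexandrov,
so the package leans on the two classical correspondences:

- every point x has a **minimal open neighbourhood** m(x), the intersection
  of all opens containing x;
- the topology is equivalent to its **specialization preorder**, with the
  convention x ≤ y iff every open containing x also contains y (equivalently
  y ∈ m(x)). This orientation is the one that makes features specialize
  location (C ≤ L) in the binding topology, makes the discrete preorder
  reflexive-only, and the indiscrete one total.

Sections are total assignments point → value with opaque string values; a
section table is a *set* of sections (duplicates merge, with a logged warning
on CSV input). A presheaf stores one table per open and an explicit
restriction map per inclusion pair. Tabular presheaves use projections, but
the maps are stored explicitly so that the functor laws (identity,
composition over all chains U ⊆ V ⊆ W, and totality/closure of each map) are
genuinely checkable — `check_functoriality` reports violations as data, and
hand-built non-tabular presheaves (e.g. with collapsing restrictions) are
first-class citizens in the sheaf checker.

Two fixed conventions:

- **F(∅) is terminal** (exactly one empty section) for every presheaf built
  here. This makes the sheaf condition over the empty cover automatic and is
  the categorically standard choice.
- Opens not contained in any generator open get the **empty table**: they are
  gaps in knowledge, which sheaving fills.

## Sheaf condition

`is_sheaf` enumerates, for every open U, every **irredundant cover** of U
(covers by non-empty opens none of which contains another). Redundant
elements never change the glue: a cover element contained in another adds
only constraints already implied by restriction, so irredundant covers
suffice on a finite space, and their number is small (bounded by the
antichains of the open-set lattice). For each cover, matching families are
enumerated by backtracking with hash-join pruning — candidates for the next
cover element are looked up by their restriction to the (largest) overlap
with the already-chosen sections — and amalgamation counting is a dictionary
lookup on precomputed restriction signatures. Separatedness (≤ 1 glue) and
gluability (≥ 1) are reported separately, with witnesses capped at 10 by
default (the total count is kept).

## Sheafification

The completion uses the minimal-open (Alexandrov) form directly rather than
the general two-step plus construction: the stalk at x is F(m(x)), so

    F⁺(U) = { (s_x ∈ F(m(x)))_{x∈U} : m(y) ⊆ m(x) ⇒ s_x|_{m(y)} = s_y }.

Minimal opens are processed largest-first so inclusion constraints become
forcings; for merely-overlapping minimal opens, agreement on the overlap is
an implied consequence of the defining condition (the overlap is a union of
smaller minimal opens) used eagerly as a hash-indexed pruning step, which
keeps large joins near-linear. Each compatible family is serialized as the
merged record p ↦ s_{m(p)}(p) over U; for projection restrictions this is a
bijection between families and records (a collision would mean two families
differ at some m(x) yet agree as functions, which projections forbid; the
code asserts this and raises on genuinely non-serializable inputs).
Restrictions of F⁺ are again projections, the unit maps s to the record of
its own germs, and the result is re-verified with `is_sheaf` before being
returned — the sheaf property of the output is enforced, not assumed.

Per-open diagnostics: `rows_added = |F⁺(U)| − |unit image|` (inferred
knowledge) and `rows_merged = |F(U)| − |unit image|` (input rows identified
by the unit; zero for separated inputs).

`check_universal_property` verifies unique factorization through the unit by
brute force: given a sheaf G and a natural φ: F → G, it counts natural
ψ: F⁺ → G with ψ∘unit = φ, enumerating component maps over opens in
decreasing size with values forced by φ and by naturality against
already-assigned larger opens, and backtracking over the residual free
choices (early exit once two solutions exist). The enforced bounds — at most
4 points and 6 rows per table, plus a node budget — keep the enumeration
honest about being exhaustive; beyond them a `SizeError` is raised rather
than a partial answer returned.

## Demos and their parameters

**Cards.** The standard 13 rank symbols and 4 suit symbols are the package
defaults. Discrete topology: generators are the two one-column tables;
completion yields 52 global rows, all added by sheaving. Indiscrete: the only
generator is the known-cards table over {R, S} and the completion is the
identity (the canonical cover of the full set is itself).

**Binding.** The four-location example — colours (red, red, blue, red),
orientations (hor, hor, hor, ver), frequencies (low, high, low, low) — is
shipped as `example_feature_tables()`. `triple_conjunction` folds binary
pullbacks over {L} (two pullbacks for three tables); since the natural join
is associative and commutative, the fold order is irrelevant, which the
tests check against a one-shot n-ary join oracle.

**Stereo.** `triangulate` solves the 2×2 system
left_eye + l·(cos λ, sin λ) = right_eye + r·(cos ρ, sin ρ); the determinant
is sin(λ − ρ), and |sin(λ − ρ)| ≤ 1e−12 is treated as parallel. The printed
ray formulas pass both rays through a common origin; the implementation takes
explicit eye positions (defaults: left at the origin, right at (baseline, 0),
baseline 1 in the same length units as the target) and reduces to the pure
ray form when both eyes coincide. Negative solved distances attach a
`BehindEyesWarning` rather than an error, since the algebraic intersection is
still well defined. In the discrete form, distance–position relation tables
are built over a finite grid and positions are rounded to a configurable
number of decimals (default 9) before joining; the convergence checks match
the rounding resolution to the grid spacing (decimals d for spacing 10⁻ᵈ), so
the glued positions track the analytic intersection to within one grid step.

## Synthetic fixtures

`generate_fixture` draws a random relation with a given edge probability,
closes it reflexively-transitively, and takes the up-set topology — valid by
construction, discrete at probability 0 and indiscrete at 1 — then attaches
1–3 rows over randomly chosen generator opens from a small symbol alphabet
(defaults: 3 points, edge probability 0.3, alphabet {a, b, c}, 2 generators).
Identical specs produce byte-identical bundles. These fixtures exercise the
algebraic laws (join commutativity/associativity/idempotence, projection
functoriality, sheafification idempotence and universality) across the whole
spectrum of 2–4-point Alexandrov topologies; they do not emulate any
particular empirical data set — values are arbitrary symbols — so passing
them demonstrates the correctness of the constructions, not the fit of the
model to behavioural data. Sizes are kept small deliberately: the sheaf
condition and the universal-property search are exponential in general, and
the point of the batteries is exhaustive verification at sizes where
exhaustiveness is real.

## Numerical and design choices

- Canonical ordering everywhere output is ordered (opens by size then label,
  rows by value tuple) makes CLI output and saved bundles byte-reproducible.
- Values are opaque strings; numeric data must be formatted before entering a
  table (the stereo demo's rounding convention is exactly this).
- `pullback(t1, t2, over)` requires `over` to lie inside the attribute
  overlap and computes the join; when `over` is a proper subset of the
  overlap, merged records necessarily also agree on the rest of the overlap,
  so the apex is the joint-agreement table.
- Angles are radians in the library; the CLI accepts `--degrees`.
- Known limitations: no infinite or non-Alexandrov spaces; no presheaves
  valued outside sets; no topology inference from data; the universal
  property verifier is exhaustive only within its stated bounds.
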