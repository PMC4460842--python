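# Methods

This note documents the models, parameters and design choices behind `p3rl`,
and what the synthetic evaluation does and does not demonstrate.

## Protocol model and assumptions

The package assumes a three-party setting: two sites (A, B) hold extracts on
partially overlapping persons, keyed by site-local identifiers; a linkage
centre (C) is trusted to run the matching but must never see plain PII. All
confidentiality guarantees are protocol-level, not cryptographic-adversary
level: the threat model is accidental or procedural disclosure to honest
parties, not an adversary mounting frequency or constraint-satisfaction
attacks on the Bloom filters. Hardening against such attacks (salting,
record-level composites, noise) is deliberately out of scope.

Each person is assumed to appear at most once per site, which is why the
final one-to-one resolution is valid. Clerical review of uncertain pairs is
impossible under encryption, so the `possible` band is reported but never
adjudicated.

## Masking

Masking substitutes character classes in place (digits 1–9 → `9`, ASCII
a–z → `z`, A–Z → `Z`) and preserves the cell's first character, zero,
spaces and everything non-ASCII-alphanumeric. "First character" is read at
the level of the whole cell value, not per word — either reading is
defensible, the cell-level one is simpler and leaks less. Non-ASCII letters
are treated as language-specific characters and kept, since revealing *that*
a site uses umlauts is precisely the structural signal the cleaning template
needs. Masking is idempotent and length-preserving by construction.

Day/month order in year-last date columns is inferred from cell-initial
digits (a first character of 2 or 3 can only be a day); when a masked sample
contains no such evidence the template carries both candidate patterns plus
a warning, and cleaning tries them in order (day-first preferred, the
dominant European convention). Missing-code candidates are short masked
values over the alphabet `9 . - ?` reaching ≥ 1 % frequency.

## Cleaning

Name standardization: uppercase; transliteration from a German/French table
(`ä→AE, ö→OE, ü→UE, ß→SS, é→E, …`, config-replaceable); removal of
non-alphabetic characters; all-digit tokens dropped, and short letter codes
co-occurring with digits (e.g. `DCO 1998`) dropped as registry codes — in
both cases with an audit-log count; leading nobiliary particles (`VON`,
`VAN DER`, `DE LA`, …) stripped to a separate slot; remaining tokens split
on space/hyphen into two fixed output slots per name type, extra tokens
concatenating into slot 2. Fixed slots keep the two sites' output schemas
identical, which the encryption comparability contract requires. Nickname
lookup is sex-specific and pass-through on misses — it is an aid, not a
filter. The default table ships with the package (Swiss-German/French
flavoured); real deployments should substitute a locale-appropriate one.

Dates normalize to ISO `YYYY-MM-DD`; month names resolve against a
German/French/English table; calendar-invalid values blank to missing with
an audit note. Audit logs contain rule-firing counts only, never values, so
they can travel to the linkage centre.

Template application is idempotent on its own output (already-normalized
ISO dates re-parse under an ISO fallback pattern; cleaned names are fixed
points of the name pipeline), so re-running a cleaning step cannot corrupt
data.

## Encryption

* **Bloom filters** (names): per-field, length `m` bits (default 1000,
  multiple of 4 for the hex codec), `k` hash functions (default 10), q-gram
  length `q` (default 2). Positions come from double hashing
  `p_i = (H1(g) + i·H2(g)) mod m`, `i = 1..k`, with `H1`, `H2` independent
  HMAC-SHA-256 instances keyed by subkeys derived from the site secret with
  distinct context labels. Double hashing is the standard field-level
  construction in this literature; two keyed hashes are enough for
  k-independence in practice. Q-gram boundary padding (`_`) defaults **on**
  for linkage (it weights word ends, improving discrimination of short
  names) but is exposed as configuration; note that padding roughly doubles
  a name's fill fraction and therefore the chance-collision floor of the
  Dice estimate (see "Approximation quality" below).
* **Dates**: plain year plus HMAC-SHA-256 digests truncated to 160 bits of
  the framed day (`D:13`), month (`M:05`), full date (`F:1980-05-13`) and
  the calendar-correct previous/next day. Framing prefixes prevent a day
  digest from ever colliding with a month digest. Two auxiliary digests of
  the bare two-digit day and month under a shared `X:` framing exist solely
  so the linkage centre can test day/month swaps by exact digest equality;
  they add no information beyond the dedicated sections (both are keyed
  digests of a value from a 31-element domain — the plain year printed next
  to them already narrows a date far more).
* **Validation token**: HMAC of the agreed test word under a dedicated
  subkey, packaged with the public `(q, k, m, pad, mac)` fingerprint.
  Linkage refuses to start unless both sites' tokens agree, and the failure
  reason distinguishes parameter divergence from key/word divergence without
  revealing either.

The secret key is never serialized; encrypted outputs are byte-identical
across processes and sites for identical cleaned input and configuration,
which is the cross-site comparability contract.

## Comparison cascades

Names: bit-identity ⇒ full agreement; otherwise Dice `2h/(a+b)` against a
per-variable cut-off (default 0.80) separates partial agreement from
disagreement; empty/absent filters are missing. A first/surname
transposition is flagged when both cross-comparisons reach at least partial
while the direct comparisons do not both reach it.

Dates, in strict order: (1) plain year + day digest + month digest equal ⇒
exact; (2) year equal and crossed auxiliary digests equal ⇒ day/month
swapped; (3) any full-date digest equal to the other side's ±1-day digest ⇒
±1 day — the order makes Dec 31/Jan 1 a ±1-day case even though the plain
years differ; (4) day and month digests equal and the plain years one digit
apart ⇒ year digit error, or an adjacent transposition apart ⇒ year
transposition; otherwise disagreement. Missing if either side is missing.

## Scoring

Per variable: full/exact ⇒ `w+ = log2(m/u)`; disagreement ⇒
`w- = log2((1−m)/(1−u))`; missing ⇒ 0; partial name agreement interpolates
linearly between `w-` and `w+` over the similarity band above the cut-off
(the simplest monotone choice, config-replaceable); recognized date-error
categories default to the midpoint `(w+ + w-)/2` and are individually
configurable; a flagged transposition replaces both name-slot contributions
with their midpoints. m/u probabilities are user-supplied — no EM
estimation is attempted.

Classification: weight ≥ upper ⇒ link (boundary inclusive); < lower ⇒
nonlink; else possible. One-to-one resolution is greedy by descending
weight with lexicographic tie-breaks, demoting displaced links to possible:
deterministic and auditable, near-optimal when weights are well separated.
The default thresholds (upper 14, lower 2) are derived from the weight
structure: the upper threshold exceeds the maximum score attainable without
any birth-date agreement (~13 under the default m/u), so namesakes alone
can never become links; a typical true match scores ≥ 18.

Blocking is a union of passes; records with an empty key component sit a
pass out. The default scheme — (birth year, sex), (encrypted day+month
sections), (surname filter) — means a true pair is lost to blocking only if
the year or sex disagrees *and* day or month is corrupted *and* the surname
filters differ, a conjunction of independent rare events. Pair counts above
a budget (default 10⁸) warn but do not stop.

## Synthetic data

The generator emulates: Swiss/German/French name material rich in umlauts
and accents (exercising transliteration and the cross-site `ü`/`ue`
divergence), two-surname and two-firstname packing, differing per-site date
patterns, and independent per-site corruption. Error-model defaults:
name typo 5 % per name field (one random single-character edit), nickname
substitution 5 %, first/surname transposition 1 %, missing value 2 % and
missing-code substitution 1 % (plain demographics only), and a total
date-error mass of 10 % per record — within the 6–25 % range reported for
birth-date discrepancies between linked sources — split 18 % ±1 day (the
empirically anchored share), 20 % swapped day/month, 42 % single year
digit, 20 % adjacent year transposition. Only the ±1-day share is
empirically anchored; the remaining split and all name-error rates are
declared defaults. Date corruption is applied to rendered components,
pattern-aware, so a swap is injected only where it survives as a valid
calendar date (day ≤ 12) — otherwise the record redraws another category —
and cleaning sees realistic raw strings.

What the generator does **not** emulate: demographically calibrated name
frequencies (a few hundred pool names repeat far more than real surnames
do, making the u probabilities synthetic-specific), household/twin
structure, address material, within-site duplicates, or drift between
extraction dates. Passing end-to-end tests therefore demonstrates the
correctness and internal consistency of the machinery under a realistic
error taxonomy — not linkage quality on any particular real registry, whose
m/u weights and thresholds must be re-derived.

## Numerical and evaluation choices

* Hex codec: bit 0 is the most significant bit of the first nibble;
  round-trip is exact.
* Dice on two empty filters is reported as missing, never 0/0.
* Approximation quality: with unpadded bigrams at m = 1000, k = 10 the
  Bloom Dice tracks the exact q-gram-set Dice to a mean absolute difference
  of ≈ 0.045 over random surname pairs; with padding the per-name fill
  roughly doubles and unrelated pairs acquire a chance-collision Dice floor
  of ≈ 0.06, which is a property of the fill fraction, not an error — the
  approximation measurement is therefore stated for the unpadded
  configuration.
* End-to-end problem sizes in the test suite and acceptance script —
  2,000 persons for the clean-limit check and 2 × 5,000 at 50 % overlap for
  the error-tolerant comparison — were chosen as the smallest populations at
  which blocking behaviour and collision rates are representative while the
  whole suite stays fast to iterate.
* The plain benchmark engine runs the identical pipeline with equality /
  edit-distance comparators (similarity `1 − d/max(len)`) on cleaned plain
  values; the encrypted-vs-plain F1 gap (≈ 0.004 under the defaults)
  quantifies what running encrypted costs.

## Known limitations

Security is bounded by the Bloom-filter literature's known attacks; no
salting or record-level hardening is provided. Date comparison is limited to
the encrypted-testable error categories — a single wrong digit in day or
month cannot be detected without weakening the encryption. Multi-site
(> 2) linkage, address variables, phonetic fallbacks and file compatibility
with external linkage software are out of scope.
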