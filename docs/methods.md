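# Methods

This note documents the semantics the engine implements, the numerical
and design choices made where the language description left room, and
what the synthetic test data does and does not cover.

## Data model

A signal track is a named multiset of intervals over chromosomes.
Coordinates are stored 1-based and both-ends inclusive throughout the
engine; `length = chrend − chrstart + 1` (forced by inclusive ends).
All conversion to on-disk conventions happens at the I/O boundary:
BED and bedGraph are 0-based half-open on disk, so loading maps
`start_disk + 1 … end_disk` and writing inverts it; WIG is already
1-based (`span` defaults to 1; `variableStep` positions start
span-length intervals). BED files carry no signal value — intervals
load with `value = NULL` and columns 4–6 become the metadata
attributes `name`, `score`, `strand`. The internal TSV dump is
lossless (a `##types` header line preserves attribute types).

NULL semantics follow SQL: arithmetic over NULL yields NULL,
comparison predicates over NULL (and over NaN, which `distance`
returns across chromosomes) are false, aggregates skip NULLs and
`COUNT(*)` counts rows. Duplicate intervals are preserved (multiset
semantics) except under `SELECT DISTINCT`. Track and metadata
attribute names are case-sensitive except the four mandatory names.

Chromosome-end bounds are not checked on load — a chromosome-sizes
file is consulted only when `generate bins with length` needs it.

## Interval relations

The eleven relations are total-function predicates that are false
across chromosomes. `is upstream of` / `is downstream of` require the
anchor's (second interval's) strand to be known and the first
interval's strand to match it or be unknown ('.'); with a compatible
strand pair they reduce to `precedes`/`follows`, so overlapping
intervals are never upstream/downstream of each other. A missing
strand attribute reads as '.'. `distance` is symmetric, 0 exactly on
overlap, and adjacency gives 1. `is closest to each` anchors on the
second track: for each of its intervals all minimum-distance partners
from the first track are emitted (ties retained, empty if the first
track has no interval on that chromosome).

Zero-length intervals cannot exist (`chrend ≥ chrstart ≥ 1`), so no
degenerate tie-breaking arises.

## Value derivation

Deriving the value of a created interval takes three steps:

1. **Location shares.** Under EACH each location of an input interval
   owns the full value; under TOTAL it owns `value/length`. The
   grammar keyword `all` and the alias `total` both select TOTAL.
   NULL-valued inputs contribute nothing to values but keep their
   geometry (they still join, split and merge positionally).
2. **Per-location combination** with the chosen `vd_*` operation.
   Applicability follows the operator arity: `coalesce`, `discretize`
   and `project` combine one-or-more same-track values and admit
   {sum, avg, product, max, min} (`vd_avg` divides by the number of
   covering valued intervals at that location, which varies along the
   output); `intersectjoin` combines exactly v1 and v2 and admits all
   nine; `exclusivejoin` admits only `vd_left`. Disallowed
   combinations are rejected at check time. `vd_quotient` with v2 = 0
   anywhere makes the affected output NULL; for the other binary
   operations a NULL required operand makes the output NULL.
3. **Averaging** over all locations of the output interval. Locations
   covered by no valued input contribute 0 to this mean — this is the
   bin/target default-0 rule; for coalesce/discretize/intersectjoin/
   exclusivejoin outputs every location is covered by construction
   unless all covering inputs are NULL-valued.

Without a value clause, created intervals get `value = NULL`
regardless of geometry.

The engine computes steps 1–3 on breakpoint segments (contributions
are piecewise constant), in double precision, with the step-3 mean
taken as (weighted segment sum)/length without compensation — outputs
are short, and agreement with the dense oracle is asserted to 1e-9
relative tolerance. `per_location_oracle` executes the same three
steps on explicit per-position numpy arrays; it is test-only and
refuses spans above 10⁶ positions.

## Track operators

All operators work per chromosome on sorted intervals (sort by start,
then end; outputs ordered by natural chromosome order, start, end).
The Cartesian-product formulation is the specification; the
implementation uses merge/sweep scans.

* `coalesce` merges each maximal transitively overlapping-or-adjacent
  group into `[min start, max end]`; outputs are pairwise
  non-overlapping and non-adjacent.
* `discretize` cuts each covered block at every input start and every
  input end + 1; outputs may be adjacent exactly where inputs were,
  and coverage is preserved. Discretize-then-coalesce returns the
  coalesce geometry.
* `project on` copies the target's positions (track intervals or
  generated bins) and derives values from the overlapping first-track
  intervals; untouched targets get 0 with a value clause, NULL
  without. With `metadata`, attributes are inherited from the target —
  the track that defines the output positions.
* `generate bins with length b` tiles `[1,b], [b+1,2b], …` per
  chromosome, truncated at the chromosome length from the configured
  sizes file. Contributors are found by per-interval bin-index
  arithmetic; bins are emitted for the whole genome but never paired
  against intervals exhaustively.
* `intersectjoin` emits one output per overlapping pair (an interval
  overlapping k partners yields k outputs); metadata, when requested,
  comes from the first track's member of the pair.
* `exclusivejoin` subtracts the second track's merged coverage from
  each first-track interval; a piece may survive intact, vanish or
  split. Metadata comes from the first track.
* `UNION ALL` concatenates tracks with identical schemas, keeping
  duplicates; chains fold left.
* `coalesce`/`discretize` never inherit metadata (only the three
  two-track operators name a donor track).

## Query semantics

A multi-track FROM is a chromosome-by-chromosome Cartesian product.
LEFT/RIGHT/OUTER joins pad at **whole-chromosome** granularity: a
chromosome present only on the kept side contributes its intervals
once each, with the other side's columns NULL — and such padded rows
are not filtered by the WHERE predicate (this matches the worked
outer-join table and differs from SQL's per-row outer join; it is the
single most error-prone semantic in the language). `ORDER BY` is
ascending only (the grammar has no ASC/DESC) and stable; output rows
for `SELECT *` name the first track's columns plainly and later
tracks' as `<alias>_<attribute>`. Aggregates are COUNT/SUM/AVG/MIN/MAX
plus COUNT(*); non-aggregated select fields must appear in GROUP BY
(SQL's rule, adopted for the unstated case).

Multi-statement scripts run in one session; intermediate statements
store results via `CREATE TRACK … AS`, later statements see them, and
the final query's result is returned. The checker validates a whole
script up front (tracking tracks that earlier statements will create),
so a rejected script executes nothing. A query result can be used as a
track only if it has the four mandatory attributes; otherwise using it
as one is an error. `FOR TRACK IN` loops cannot nest.

The printed grammar allows only a single AND/OR repetition and binary
arithmetic chains; unbounded repetition (standard SQL) is implemented,
reading the printed productions as eliding Kleene stars. Two worked
constructs absent from the printed productions — `length()` as a
select field and `LEFT/RIGHT/OUTER JOIN` — are grammar extensions
recorded on the AST.

### Optimizer

Three passes, all result-preserving (asserted by tests comparing
against the literal product evaluation): early attribute pruning on
table scans; rewriting the two-track product into a sorted proximity
scan when a top-level conjunct demands overlap/adjacency (the scan
enumerates pairs within a ±1 window, a superset of satisfying pairs,
then applies the full predicate); and non-materialized bin projection.
Chromosomes are independent units of work throughout — operators share
no mutable state across chromosomes, and per-chromosome outputs are
concatenated in canonical order.

## Catalog

The multi-user metastore of a server deployment is replaced by a
single-user registry: an in-process `Catalog`, optionally loaded from
a YAML file listing per track its name, file path, format, category
and free-form selection attributes. Track selection for `FOR TRACK IN`
filters one category by conjunctive `=` / `LIKE` conditions (SQL
wildcards `%`, `_`; the pseudo-attribute `name` matches the track
name) and returns tracks in lexicographic name order, making loops
deterministic.

## Synthetic data

`make_fixture_tracks` reproduces the two worked 3-row join tracks
exactly and provides parameterized analogues of the operator-figure
geometries (overlap chain + isolated interval for coalesce, an
adjacent pair for discretize, covered/uncovered targets for project,
one-to-many overlap for intersectjoin, survive/vanish/trim/split for
exclusivejoin). `generate_random_track` draws integer coordinates and
lengths from a seeded generator (integer arithmetic, reproducible
across platforms), with a configurable fraction of intervals forced to
overlap their predecessor and value distributions including constant 1
(the unit-valued acceptance condition) and constant NULL (BED-like
input).

What this emulates: small, dense interval sets with controlled overlap
structure on a few short chromosomes. What it does not: genome-scale
track sizes, realistic signal autocorrelation, chromosome-length
heterogeneity, or malformed real-world files. Passing tests therefore
demonstrate semantic correctness of the operators and query engine,
not performance at data-center scale — the engine is deliberately
desk-scale (single machine, per-chromosome partitioning; distributed
execution is out of scope).

Test problem sizes: the oracle-equivalence suite uses 500 random
instances of ≤ 50 intervals with coordinates ≤ 10⁴ per instance,
checked under every legal operator × vd × model combination; join
equivalence uses 200 random two-track queries of ≤ 30 intervals per
track; conservation uses 100 random tracks projected onto 128-bp bins;
the relation truth tables are exhaustive over all 1275 intervals of a
length-50 grid (1.6 M ordered pairs), with an independent bitmask
position-set oracle.

## Known limitations

* Across-chromosome joins are unsupported by design; the documented
  workaround is renaming chromosomes into an attribute before joining.
* The closest-interval predicate must be the entire WHERE clause (the
  grammar places it as an alternative to the predicate tree).
* `ORDER BY` on expressions (rather than attributes) is not in the
  grammar and not supported.
* No cost-based optimization, spill-to-disk, or sub-chromosome
  parallelism; bigWig/bigBed are out of scope (text formats only).
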