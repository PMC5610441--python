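# stql

A desk-scale engine for the **Signal Track Query Language (STQL)** — an
SQL-like declarative language for analyzing genomic signal tracks: sets
of genomic intervals carrying numeric values (ChIP-seq peaks, read
coverage, methylation signal, …) plus optional metadata such as strand.

Analysts working with signal tracks spend much of their time on
plumbing: intersecting peak sets, merging enhancer calls, binning
coverage, subtracting blacklists, computing distances to the nearest
gene. STQL expresses these as short declarative queries instead of
bespoke scripts, and this package executes such queries on a single
machine over BED / bedGraph / WIG files.

## The language in brief

Every track is a multiset of intervals with four mandatory attributes
`chr`, `chrstart`, `chrend` (1-based, both ends inclusive) and `value`
(numeric or NULL), plus free metadata attributes. On top of SQL's
SELECT / FROM / WHERE / GROUP BY / ORDER BY, the language adds:

* **Eleven positional relations** — `overlaps with`, `coincides with`,
  `contains`, `is within`, `is adjacent to`, `is prefix of`,
  `is suffix of`, `precedes`, `follows`, and the strand-aware
  `is upstream of` / `is downstream of`; plus `distance(I1, I2)`
  (0 on overlap, gap size otherwise, NaN across chromosomes) and the
  `is closest to each` relation with all exact ties retained.
* **Track-creating operators** — `coalesce` (merge transitively
  overlapping-or-adjacent intervals), `discretize` (split covered
  regions at all input boundaries), `project … on` a track or on
  `generate bins with length b` genome tilings, `intersectjoin`
  (per-pair intersections), `exclusivejoin` (coverage subtraction) and
  `UNION ALL`.
* **Two-model value derivation.** An interval's value is interpreted
  under the **EACH model** (every genomic location owns the full value)
  or the **TOTAL model** (each location owns an equal share,
  `value/length`). The value of a resulting interval is derived in
  three steps: (1) distribute each input value to its locations by the
  model; (2) combine the contributions at every location with one of
  `vd_sum, vd_avg, vd_diff, vd_product, vd_quotient, vd_max, vd_min,
  vd_left, vd_right`; (3) average over the locations of the resulting
  interval. For example, intersecting two unit-valued tracks with
  `vd_sum` under EACH gives every output value `1 + 1 = 2`; under
  TOTAL it gives `v1/len(I1) + v2/len(I2)`.
* **DDL/DML and looping** — `CREATE TRACK` (empty or `AS` a query),
  `DROP TRACK`, `LOAD DATA LOCAL INPATH`, and `FOR TRACK x IN
  (category, conditions…)` to repeat a query over all tracks of a
  catalog category, either combined with `UNION ALL` or stored per
  track.

Joins of multiple tracks are evaluated chromosome by chromosome, and
LEFT/RIGHT/OUTER joins pad whole chromosomes absent from one side with
NULLs. The optimizer prunes unused attributes early, replaces the
Cartesian product with a sorted proximity scan whenever the predicate
demands overlapping/adjacent pairs, and computes bin projections by
per-interval bin arithmetic — never changing results, a property the
test suite asserts.

## Worked example

```bash
stql fixtures /tmp/fx          # write the built-in example tracks
stql run "SELECT * FROM T1, T2 WHERE T1.chr = T2.chr" \
     --catalog /tmp/fx/catalog.yaml
```

prints the chromosome-wise join of the two example tracks:

```
chr     chrstart  chrend  value  T2_chr  T2_chrstart  T2_chrend  T2_value
chr1    101       200     10     chr1    401          500        40
chr1    201       300     20     chr1    401          500        40
chr2    301       400     30     chr2    501          600        50
```

Each row pairs one interval of `T1` with one same-chromosome interval
of `T2`; chromosome 3 is absent because `T1` has no intervals there
(use `RIGHT JOIN` to keep it as a NULL-padded row). The same session
from Python:

```python
from stql import Session
from stql.fixtures import make_fixture_catalog

session = Session(make_fixture_catalog())
result = session.run(
    "SELECT * FROM fig_intersect_t1 INTERSECTJOIN fig_intersect_t2 "
    "WITH vd_sum USING EACH MODEL")
print(result.rows)
# [('chr1', 151, 200, 2.0), ('chr1', 221, 260, 2.0),
#  ('chr1', 421, 460, 2.0), ('chr1', 551, 600, 2.0)]
```

Both fixture tracks are unit-valued, so every pairwise intersection
carries the value 2 under `vd_sum`/EACH — the canonical sanity check
for the value-derivation semantics.

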