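# Methods

## The filter

All three engines compute the same estimator on a 2D intensity image `Y`
(`m` rows × `n` columns, pixel `(x, y)` = column, row, 0-based):

```
X̂(p) = Σ_{q ∈ N_p ∩ image} w(p,q) Y(q) / Σ_{q ∈ N_p ∩ image} w(p,q)
w(p,q) = exp( − d(p,q) / (h² (2B+1)²) )
d(p,q) = Σ_{(Δx,Δy) ∈ [−B..B]²} |Y(p+Δ) − Y(q+Δ)| · G(Δx,Δy)
G(0,0) = 2,  G(Δx,Δy) = 1/(Δx²+Δy²) otherwise
```

Two points deserve emphasis because they differ from the textbook NLM:

* the patch metric uses the **absolute** intensity difference, not the
  squared difference — this variant is implemented exactly as defined and
  deliberately not "fixed";
* the self weight is `exp(0) = 1` (no max-weight substitution).

The exponent's denominator is the per-pair distance normalized by patch
area, `h²·(2B+1)·(2B+1)`.

## Parameters

| name | meaning | default | notes |
|------|---------|---------|-------|
| `T`  | search radius (window `(2T+1)²`) | 40 (81×81) | large windows are what make LDCT artifact suppression work — and what makes cost the issue |
| `B`  | patch radius (patch `(2B+1)²`)   | 4 (9×9)    | also sets the asymptotic acceleration `2B+1` |
| `h`  | smoothing strength, intensity units | 10      | scale-relative; the default assumes a 0–255 display scale (the phantom's scale) |

## Border policy

The filter definition is silent at image borders, so one policy is fixed
for all engines (it is part of the equivalence contract):

* candidate partners `q` outside the image are **excluded** from the
  average (window truncation) — no invented intensities ever enter the
  weighted mean, and the normalization stays well defined;
* patch differences are evaluated on the **edge-duplicating mirror pad**
  (`[1,2,3] → [1,1,2,3,3]`) of width `B` (conceptually; the decomposed
  engines pad wider internally so shifted whole-plane reads stay in
  bounds — symmetric padding is layer-stable, so the values agree).

## The three engines and the charging scheme

Costs are *charged operations*: a unit per fresh image fetch from the
(conceptually global) image buffer or per constant-cost plane step.
Reads of cached row sums are free — the model is memory-bound, which is
precisely what makes row caching pay. Counters track fetches, multiply-adds
and exponentials separately, and accumulate the abstract charge as an exact
rational per pixel.

* **naive** (`reference`): literal triple loop, offsets visited row-major
  (`i_y` ascending, then `i_x`). No counters; it is the oracle.
* **conventional**: for every one of the `|N| = (2T+1)²` offsets, four
  plane passes — signed center differences (charge 1), patch weights read
  from the difference plane at patch-shifted positions (charge `(2B+1)²`),
  accumulation into running sums U3/U4 (charge 1) — plus the final
  division (charge 1). Total `|N|((2B+1)²+2)+1` per pixel. The difference
  plane lives on the padded domain so the displaced reads are defined at
  borders. Out-of-bounds partners record weight 0 rather than padded
  intensities, preserving the truncation semantics.
* **optimized**: per half-window offset, a row-cache pass (charge `2B+1`:
  the `2B+1` fresh fetches of a row pair; the `B+1` kernel re-weightings
  are arithmetic on cached values), a patch-weight pass summing `2B+1`
  cached values per pixel (charge `2B+1`), and a symmetric accumulation
  crediting each weight forward *and* backward (charge 1). The forward and
  backward contributions are gated on partner in-boundedness
  independently — that is what makes the half traversal reproduce the
  truncated-window result exactly. Total
  `0.5·|N|·(2(2B+1)+1)+1` per pixel.

### Charging conventions adopted where the model is schematic

* The per-pass unit charges (the `+2` and `+1` constants) are adopted as
  given by the closed forms; the model does not itemize which arithmetic
  each unit covers, and neither do the counters.
* The half offset list contains exactly `((2T+1)²−1)/2` offsets (all
  `i_y > 0`, plus `i_y = 0, i_x > 0`); the self offset is processed once,
  separately, and is charged **half** a pass-unit — it is its own
  symmetric partner. This convention makes the counted total equal the
  closed form `0.5|N|(2(2B+1)+1)+1` exactly (half-integers and all), which
  the tests then verify against the instrumented engines.
* The row cache is nominally `m × n × (B+1)`; the implementation allocates
  `(m+2B) × n × (B+1)` so the border rows consumed by patch aggregation at
  the image edge are cached under the same indexing. The kernel couples
  `Δx` and `Δy`, so the cache stores kernel-pre-weighted row sums for all
  `B+1` vertical indices rather than raw row sums (raw sums could not be
  re-weighted after summation).

### Behavior of the finite ratio

`conventional/optimized` increases monotonically with `|N|` toward
`2((2B+1)²+2)/(2(2B+1)+1)` — `83/9.5 ≈ 8.74` at `B = 4`, just below the
asymptotic simplification `2B+1 = 9`. For `B ≤ 1` the limit actually
*exceeds* `2B+1` (the `+2` overhead dominates the small patch), so the
"finite ratio below the asymptote" property is only claimed and tested for
`B ≥ 2`.

## Numerical choices

* All arithmetic is float64 regardless of input bit depth; the engines are
  required to agree with the oracle to 1e-10 relative, and in practice
  agree to ~1e-14 (same arithmetic, re-associated).
* Offset order and accumulation order are fixed, so repeated runs are
  bit-identical; the "parallel pass" contract is only that results are
  independent of internal chunking, which is tested by split accumulation.
* `finalize` refuses a zero weight sum — impossible once the self offset
  (weight 1) is accumulated, so it signals an internal bug, not bad data.
* 8/16-bit output is clipped to the type range and rounded half-to-even.

## The phantom: what it emulates and what it does not

The generator produces a deterministic ellipse phantom (abdomen-like body
outline, two organs, a low-density pocket, a small bright lesion) on a
0–255 scale, then degrades it with seeded i.i.d. Gaussian mottle
(default SD 15) and 8 additive straight ridges (~1.5 px FWHM, amplitude 25)
through the image center at seeded random angles — the visual character of
low-dose degradation: grain plus directional streaks.

It does **not** simulate acquisition: no projection/FBP physics, no Poisson
photon statistics, no tissue-dependent noise correlation, no beam
hardening. Passing the behavioral check (filtering reduces MSE to the
clean phantom versus the degraded input, for 5 seeds at `T=10, B=2, h=10`)
therefore shows the filter removes structured synthetic degradation; it
does not certify clinical image quality. The default phantom side of 128
pixels is the package's demo/verification size; the engines themselves are
size-agnostic.

## Scope and limitations

* 2D only; the plane-wise 3D extension of the row cache is out of scope.
* No GPU code: the shared-memory design is represented by the counted
  cost model and an execution-order-independence contract, which is what
  makes the acceleration claim checkable on any machine.
* Wall-clock speed is reported by the CLI for information only and never
  asserted; the naive engine is intentionally slow.
* `h` is scale-relative: images are filtered in their stored intensity
  units, and `h=10` presumes display-scale values. Rescale `h`, not the
  image.
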