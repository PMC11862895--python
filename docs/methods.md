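# Methods

This note records the models, conventions and numerical choices behind
each stage, what the synthetic generators do and do not emulate, and the
known limitations.

## Coordinates and the organization table

All coordinates are 1-based and inclusive on both ends, on the heavy
(H) strand; light-strand (L) features are reverse-complemented on
extraction. Features spanning the circular origin are rejected rather
than silently mishandled — in the genome this package is organized
around, position 1 is the first base of tRNA-Phe and nothing wraps.

*Continuity* between consecutive features (in coordinate order,
regardless of strand) is `start − prev_end − 1`; the first feature's
value is its offset from the origin (`start − 1`). This convention
reproduces every value of the published organization table we
spot-checked (ND1 +5, tRNA-Ile −1, tRNA-Gln −3, ATP6 −43, tRNA-Cys +31,
ND6 −17) and yields the telescoping identity
`Σ(size + continuity) = end of last feature`, which the tests assert
exactly.

Stop-codon class is decided by CDS length mod 3: a multiple of 3 must
end in a vertebrate-mitochondrial stop (TAA/TAG/AGA/AGG; a complete
terminal codon outside this set flags the row instead of raising),
remainder 2 is a truncated `TA`, remainder 1 a truncated `T`. Truncated
stops are reported, never "repaired" to UAA; translation is out of
scope.

## Composition

Contents and skews use only unambiguous bases in the denominator (N
counts toward feature length, not composition). A skew with a zero
denominator is defined as 0. "Mean PCG A+T" is the unweighted mean of
per-gene percentages — published per-class averages rarely state whether
they weight by length — and the length-weighted value over the
concatenation is reported alongside. Percentages are written with two
decimals in TSV output.

## Codon usage

The genetic code is fixed to the vertebrate mitochondrial table
(translation table 2), which is what makes assignments like AAU-Asn,
AUA-Met and UGA-Trp come out right; Met and Trp are therefore 2-codon
families (AUA/AUG, UGA/UGG) and Ser a 6-codon family. Counting
conventions, recorded in the output header: each PCG is read on its
coding sense; trailing incomplete codons (truncated stops) are dropped;
stop codons never enter the usage table (the terminal stop by
convention, and any overlap-forced internal stop for consistency);
start codons are counted as ordinary codons, there being no standard
reason to special-case them. RSCU(c) = count(c) × k / Σ_family counts;
an unobserved family reports RSCU 0 for all members.

## tRNA cloverleaf assignment

Free-energy minimization is deliberately avoided: a constrained
template search is deterministic, testable, and sufficient to decide
the one question the analysis asks — does the annotated tRNA fold into
the canonical four-arm cloverleaf? The search is anchored, in order: a
7-nt anticodon loop at an occurrence of the annotated anticodon (most
paired bases wins among multiple occurrences, ties to the 5'-most); a
greedily extended anticodon stem (target 5 bp, ≥ 4 required, no
mismatches); the acceptor stem from the paired termini (7 bp, ≥ 6
matches, ≤ 1 mismatch, 0–1 unpaired 3' discriminator); a D arm in the
5' flank (stem 4 then 3 bp, loop 4–12 nt, 1–2 nt spacer to the
anticodon stem, 1–3 nt after the acceptor strand); a T arm in the 3'
flank (stem 5 then 4 bp, loop 5–9 nt, ending 0–1 nt before the acceptor
3' strand). Allowed pairs are Watson-Crick plus the G·U wobble —
standard for tRNA stems — with at most one mismatch tolerated, and only
in the acceptor stem: mitochondrial tRNAs are degenerate, but unlimited
mismatches would make "canonical" vacuous. Arms searched but not found
are reported absent; `is_canonical` requires all four.

Because the search tries the canonical geometry first, tRNAs built by
the arm-by-arm constructor (`make_trna`) are recovered at their exact
planted positions, which is what the parameter-recovery tests assert. A
canonical layout needs ≥ 66 nt under these arm sizes; the 59-nt
tRNA-Ser1 is therefore constructed with a direct D-replacement loop, as
in real mitochondrial tRNA-Ser(AGY), and folds non-canonical. The
published account likewise reports the single tRNA-Ser exception
without arm-level detail, so the assertion carried through the tests is
"non-canonical", not specifically "D arm absent".

## Distances and trees

p-distance uses pairwise deletion (sites with a gap or ambiguity in
either sequence are excluded), matching the common default of distance
tables in the MEGA tradition; the convention is stamped into output
metadata. ML distances are fitted numerically: the pairwise site-pattern
counts are scored against the model's analytic transition-probability
matrix and the time parameter maximised by bounded scalar search,
refined by locating the zero of the score function (scalar optimisers
stop near √eps; the score root is sharp to ~1e−12, which is what lets
the JC69 fit agree with −(3/4)·ln(1−4p/3) to 1e−9). K2P's κ and TN93's
α₁/α₂ are profiled on coarse-to-fine grids; TN93 base frequencies are
empirical averages of the pair. The model family defaults to TN93 —
the customary choice for such tables — with JC69/K2P selectable, and
the model name is stamped into every matrix. Divergences beyond a
model's resolvable bound are reported as infinite ("saturated"), not
raised. The closed forms kept in the package (`jc69_closed_form`,
`k2p_closed_form`) serve as independent test oracles for the numerical
route, alongside a cross-check of TN93 against R ape's moment estimator
(1% tolerance: ML and moments differ slightly on finite data).

Neighbor-joining is the standard Saitou–Nei agglomeration; a negative
branch length is clamped to zero with the deficit moved onto its sister
branch, preserving the path length between the joined nodes. The
correctness oracle is brute force: on additive matrices every quartet
is resolved by the four-point condition and compared against the splits
of the returned tree (≤ 5 taxa), plus a topology cross-check against
dendropy's NJ. Bootstrap resamples alignment columns with replacement
and reports, on the point-estimate tree, the percentage of replicates
containing each internal split; fixed seed ⇒ identical supports.
Bayesian inference and full ML tree search are intentionally absent:
the distance trees approximate, not replicate, likelihood/Bayesian
phylogenies, and no interspecific numeric value is asserted anywhere —
the published congener sequences are not distributed here.

## Bioacoustics

The generator synthesises descending FM sweeps (linear or hyperbolic)
with a Tukey (25% taper) amplitude envelope at 384 kHz sampling, spaced
by the inter-pulse interval, plus white Gaussian noise at the requested
SNR (peak pulse power over noise power). Ground truth is returned per
pulse; the truth "peak frequency" is the sweep midpoint — for a
near-flat chirp spectrum the spectral argmax legitimately wanders
within the swept band, so tests hold the measured peak to the band, not
the midpoint.

Measurement constants (all in `AnalysisConfig`): Hann window of 256
samples (resolution bandwidth 1.5 kHz at 384 kHz), hop 64 samples
(0.167 ms), FFT zero-padded to 2048 with parabolic interpolation of
spectral peaks; detection threshold −24 dB relative to the recording's
peak band-limited energy envelope, with sub-threshold gaps under 1 ms
fused and candidates shorter than 0.3 ms dropped; ridge/envelope
inclusion cutoff −20 dB relative to the window maximum. The analysis
band is either given or estimated from the mean spectrum (extent −26 dB
from the peak, clamped above the noise floor, padded 2 kHz). Duration
and onset come from the cutoff crossings of the smoothed analytic
envelope of the band-passed window — sample-level resolution, rather
than spectrogram frames, because frame-span durations are biased by
roughly a window length. IPI is onset-to-onset (at IPIs two orders
larger than durations, the alternative conventions are
indistinguishable); SD is the sample SD (n−1).

Recovery guarantees verified by the tests, at SNR ≥ 20 dB and IPI ≫
duration: exact pulse counts; start/end frequency within one resolution
bandwidth (1.5 kHz, typically ~0.3 kHz in practice — the residual bias
comes from the envelope taper hiding the outermost milliseconds of the
sweep from the first/last usable frames); duration within one hop.
These commercial-detector-style definitions are this package's own;
absolute agreement with any proprietary analysis software is not
claimed. Relatedly, "bandwidth" here is the spectrogram-ridge extent,
which is systematically smaller than start−end under edge tapering —
published bandwidth figures measured by other definitions are not
comparable and are not asserted.

## Synthetic genome generator

The generator's default conditions are the published organization
itself: the 38-feature template (13 PCG / 22 tRNA / 2 rRNA / D-loop)
with the published lengths, strands, continuities (including the −43
ATP8/ATP6 overlap), start codons, truncated stops and anticodons, and a
base bias of A 0.285 / C 0.271 / G 0.130 / T 0.314 — matching the
reported PCG composition (A+T ≈ 59.9%) with mildly negative AT skew and
strongly negative GC skew, as is typical of vertebrate mitochondrial
coding strands.

Layout is left-to-right from continuity targets. Overlaps are resolved
by reservation: PCG start/stop codons are written first (a later
constraint landing on a reserved base must agree exactly — this is what
makes the real template generatable, e.g. COX3's ATG sharing ATP6's
stop base); tRNA bodies are then constructed arm-by-arm, with any
already-written overlap positions passed to the constructor as fixed
bases (satisfied by deterministic redraw); random PCG bodies fill the
rest codon-by-codon, avoiding in-frame stops wherever all three bases
are free. Truth tables (organization rows, per-gene base counts, pooled
codon counts, planted tRNA structures) are emitted alongside, and an
engulfing overlap or irreconcilable constraint rejects the spec.

What the generator does *not* emulate: real sequence content (bodies
are i.i.d. draws, not homologs), substitution processes along a tree,
rRNA secondary structure, repeats or heteroplasmy in the control
region. Passing tests therefore demonstrate that the *derivations* —
tables, counts, folds — are correct on genomes whose answers are known,
not that any biological inference holds on real data.

## Problem sizes

Defaults used throughout the tests and the acceptance script: full
16,933-bp genomes (100 seeds for the round-trip property), 3–20-pulse
trains at 384 kHz (50 seeded draws for acoustic recovery), alignments
of 400–1,500 sites, 5-taxon trees for the brute-force oracle, and
100-replicate bootstraps — small enough to run comfortably on one CPU,
large enough that every statistic is in its asymptotic regime.
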