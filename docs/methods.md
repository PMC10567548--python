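# Methods

## Assay model

The pipeline targets deterministic-barcoding-in-tissue (DBiT) spatial
CITE-seq data. Two paired-end libraries are produced from one tissue
section: an RNA library (Read 1 = cDNA insert) and an ADT library (Read 1 =
antibody tag followed by poly(A)). In both, Read 2 reads through the ligated
barcode construct: UMI, spatial barcode B (column), ligation linker, spatial
barcode A (row). A pixel is the intersection of one A-channel and one
B-channel; its address code A<sub>i</sub>B<sub>j</sub> is the pair of
whitelist indices, labelled `{row}x{col}`.

Exact segment lengths are a panel-design choice, so the Read-2 layout is a
config object. Defaults: 10-nt UMI, 8-nt spatial barcodes, 30-nt linker,
15-nt ADT tags — conventional sizes for this family of assays; all
overridable via the `layout` config block.

## Simulator

The generator is first-class, tested code; its defaults define the
conditions the test suite measures under.

- **Tissue model.** A grid of ≤50×50 pixels partitioned exactly into 3–7
  spatial domains. Each domain has per-pixel mean molecule counts per gene
  and per antibody; a global `background_rate` (default 0.05
  molecules/pixel/antibody) adds nonspecific ADT binding to every antibody,
  including isotype controls, whose specific means are zero. The demo
  presets (`spleen_like`, `tonsil_like`, `skin_like`) sketch compartment
  geometries — pulp/capsule rings, germinal-center light/dark zones,
  epidermis/dermis bands with a focal infiltrate — with one ≥10×-enriched
  marker per domain (baselines: 1.0 molecule/pixel per gene, 0.5 per
  antibody; enrichment factor 10). The `skin_like` infiltrate enriches the
  Tph trio (LAG3, PDCD1/PD-1, CXCR6) in both modalities.
- **Molecules.** Counts per (pixel, feature) are Poisson around the domain
  mean — the simplest generative model consistent with UMI-count data.
  (A negative-binomial option was considered and deferred; overdispersion
  mainly rescales the recovery statistics the tests already measure.)
- **UMIs.** Uniform random, so collisions can merge molecules. The
  recoverable truth is therefore the distinct-(UMI, feature, pixel) matrix
  (`GroundTruth.distinct_umi_matrix`), which all recovery tests use; the raw
  molecule matrix is also available.
- **Reads.** Each molecule is emitted as ≥1 read pair; the duplicate count
  is geometric with mean `pcr_duplication` (support ≥1). RNA Read 1 is a
  fixed-length (90 nt) random substring of the gene's transcript — long
  enough for unambiguous toy assignment, short enough for fast tests. ADT
  Read 1 is the tag at the layout's Read-1 offset, poly(A)-filled.
  Substitution errors are applied uniformly per base (rate in [0, 0.25)),
  each error moving to one of the other three bases. Quality strings are
  constant 'I' (Phred 40); nothing downstream reads qualities.
- **Determinism.** All randomness flows from one `numpy` generator seeded by
  `ErrorModel.seed`; identical inputs give byte-identical FASTQs.

What the simulator does **not** emulate: diffusion between microchannels,
ADT–mRNA reverse-transcription competition (beyond what profile means
encode), indels, position- or quality-dependent error rates, and the
ADT-internal UMI (see below). Passing recovery tests therefore demonstrate
correctness of the computation under a substitution-only error model, not
performance on real sequencing artefacts.

## Demultiplexing

Gates run in a fixed order with first-failure accounting, so the stats
decompose exactly: structural length check (`short_read`), linker Hamming
gate (default radius 2 on the 30-nt linker), barcode A, then barcode B
(default radius 1). `total = short_read + fail_linker + fail_bcA + fail_bcB +
ambiguous + passed` holds on every run.

Correction returns the unique whitelist entry at minimal Hamming distance
within the radius; exact matches always win; ties are dropped as ambiguous
rather than resolved arbitrarily, because a mis-assigned pixel is spatial
cross-contamination — the worst failure mode for this assay. When the
whitelist's minimum pairwise distance d_min satisfies 2·max_hamming < d_min,
a barcode carrying ≤ max_hamming substitutions can never correct to the
wrong entry; loading warns when a requested radius violates this. For speed,
per-read lookup uses a precomputed Hamming-ball table (whitelist × all
sequences within the radius); tests verify it against the exhaustive scan.

Only substitutions are modelled and corrected; reads with indels in the
barcode region are lost at the linker or barcode gate.

## Feature assignment and UMI collapse

ADT tags match the panel by the same unique-nearest rule (default radius 1,
ties dropped). RNA payloads are assigned by an exact k-mer index (default
k=31) over a toy transcriptome: a read is assigned iff its k-mers hit
exactly one gene. This is deliberately a stand-in with the same interface as
a genome aligner; externally produced `read_id → gene` tables plug in via
`assign_features(external_assignments=...)`.

UMI collapse defaults to **exact** distinct-UMI counting per
(pixel, feature) — matching the default behaviour of the feature-barcode
counting tools this mirrors. The **directional1mm** mode merges UMIs into
networks along edges u→v with Hamming(u,v)=1 and count(u) ≥ 2·count(v)−1,
growing networks from the most abundant unvisited UMI, and counts networks;
it is exposed for robustness studies, not the default. The UMI used for
deduplication is the Read-2 (spatial-barcode) UMI; ADTs also carry an
internal UMI in the real assay, but the counting convention adopted here —
and emulated by the simulator — dedupes on the Read-2 UMI, so the internal
one is not modelled.

Protein matrices retain all-zero panel rows (panel size stays structurally
visible and per-pixel protein-count QC is well defined); RNA matrices drop
never-observed genes by default. Pixels appear in output iff they received
≥1 counted molecule; an optional pixel-list filter file stands in for
image-based cropping to tissue-covered regions. A per-pixel "protein count"
means features with ≥1 UMI — no abundance threshold.

## Normalization and scoring

- **CLR** (protein): y_fp = ln(x_fp+1) − mean_f ln(x_fp+1), natural log,
  pseudocount +1 for zeros. The default margin centers within each pixel
  across features (the compositional reading of ADT data); `per_feature` is
  available since tool conventions differ between versions. Per-pixel sums
  are zero to ≤1e-9 by construction; an empty matrix is an error.
- **RNA log normalization**: y = ln(1 + scale·x/pixel_total), scale 10⁴;
  all-zero pixels map to zeros. This is intentionally lighter than
  variance-stabilizing transforms, which belong to the downstream clustering
  tools this package feeds.
- **Signature scores**: genes are deduplicated; absent genes skipped (error
  if none remain); zero-variance genes excluded; score = per-pixel mean of
  per-gene z-scores across pixels. Mean-z is the minimal defensible choice
  for a three-gene signature — no weighting or thresholding is applied, and
  the gene list is configuration (`signature_genes`), not hard-coded. The
  Tph default is {LAG3, PDCD1, CXCR6}; PD-1's gene symbol is PDCD1, and the
  shipped `protein_signature_map` routes the protein-level variant to the
  corresponding ADT ids.
- **Pseudo-bulk**: pixels with total UMI < 10 are excluded (mirroring the
  low-count cell filter used for dissociated single-cell references), then
  features are summed; raw totals and CLR of totals are returned for
  cross-platform correlation.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data: a
10×10-pixel, 20-gene, 30-ADT configuration for behavioural checks (seconds
per run) and 50×50-pixel runs with 273- and 189-antibody panels for the
full-scale structural checks (≈10⁵–10⁶ read pairs, under a minute each).
These sizes were chosen so that every property is measured at the smallest
scale at which it is meaningful: exact identities and oracle equivalences do
not grow more informative with depth, while the full-scale runs exercise the
complete barcode space and panel widths of the real assay.

## Numerical and degenerate-input choices

Hamming distance is defined only for equal lengths (length mismatch is an
error, not distance ∞). Whitelist indices are 1-based and contiguous.
Empty panels/whitelists, mixed tag lengths, duplicate tags or barcodes,
non-ACGT sequences, non-partitioning tissue domains, and out-of-grid pixels
are all rejected at validation time with the offending row/path named.
Matrices are written write-then-rename so interrupted runs never leave
truncated files; manifests record a SHA-256 hash of the canonicalized
config.

## Known limitations

- The toy transcript assigner is exact-match only; it under-assigns reads
  whose every k-mer spans an error (negligible at the simulated error rates,
  fundamental for real data — use an external aligner there).
- Exact UMI collapse inflates counts when PCR duplication and UMI-region
  errors combine (each errored duplicate mints a new UMI); the directional
  mode mitigates this at some risk of over-merging dense UMI neighbourhoods.
- Published per-pixel summary statistics of real tissue datasets depend on a
  pixel-inclusion rule (tissue cropping) that is image-derived and not part
  of this package; the pixel-filter file is the supported substitute.
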