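# lysoprof

Analysis pipeline for **Lyso-IP organelle proteomics**: rapid
immunoprecipitation of lysosomes via epitope-tagged membrane markers
(LMP-1/LAMP or CTNS-1/Cystinosin), followed by label-free quantitative
mass spectrometry. The package takes gene-level iBAQ tables — it does no
spectral processing — and provides every computational step between the
quantification table and the biological readouts:

* **Normalization & QC** (`lysoprof.proteomics`) — iBAQ → iFOT
  ("fraction of total": each gene product's iBAQ divided by the sample's
  summed iBAQ, so columns sum to 1), replicate Pearson correlation, PCA
  of samples, per-protein z-scores across conditions.
* **Enrichment calling** (`lysoprof.enrichment`) — the three-criterion
  filter defining a lysosome-enriched candidate: iFOT ≥ 10× the paired
  flow-through in **every** IP replicate where the protein is detected
  (≥ 2 detections), and mean IP iFOT > 2× the mean of non-tag bead
  controls. Zeros are semantic (undetected); absence from the
  flow-through counts as infinite enrichment.
* **Tissue heterogeneity** (`lysoprof.tissue`) — marker-normalized
  ratios (protein iFOT / LMP-1 iFOT per replicate) compared between
  whole-body and tissue-specific IPs; Groups I (comparable), II (tissue
  increase, p < 0.05), III (tissue decrease, p < 0.05), IV (absent in
  tissue), by unpaired two-tailed Student's t-test.
* **Candidate-set comparison** (`lysoprof.comparative`) — Venn/upset
  counts, overlap percentages (half-away-from-zero rounding), annotation
  breakdowns, and the two-sample test for equality of proportions
  (pooled chi-square, df = 1).
* **Radial organelle positioning** (`lysoprof.spatial`) — given a convex
  cell outline and nucleus outline, each cytosolic pixel's fractional
  position f between the nuclear boundary (0) and the cell boundary (1)
  along the ray from the nucleus centroid assigns it to one of R shells
  (default 8); per-shell normalized mean intensity and cumulative
  intensity distributions quantify perinuclear vs peripheral clustering.
* **Synthetic data** (`lysoprof.simulate`) — ground-truth generators for
  both the proteomics and the imaging arms, so every stage is
  benchmarked without any deposited raw data.

## Worked example

```python
import lysoprof as lp

# Simulate a whole-body Lyso-IP experiment: 1000 proteins, 100 truly
# lysosomal with median 50x capture enrichment, 4 IP/FT pairs, 3 non-tag
# controls, 20% replicate noise.
params = lp.ProteomeSimParams(seed=1)
ibaq, truth = lp.simulate_lysoip_experiment(params)

ifot = lp.to_ifot(ibaq)                      # columns now sum to 1
candidates, records = lp.call_candidates(ifot, "WT")
lyso = set(truth.index[truth])
tp = len(candidates.members & lyso)
print(len(candidates), tp / len(lyso), len(candidates) - tp)
# 100 1.0 0
```

The caller recovers all 100 truly lysosomal proteins with no false
positives under the benchmark conditions. On the imaging side:

```python
cell = lp.CellSimParams(seed=23, n_puncta=2000, image_shape=(256, 256),
                        radial_distribution=("uniform",))
img, geom, puncta = lp.simulate_cell(cell)
profile = lp.radial_profile(img, lp.assign_regions(geom, R=8))
print(profile.cumulative_norm.round(3))
# [0.118 0.238 0.371 0.505 0.636 0.775 0.895 1.   ]
```

With puncta placed uniformly in fractional radial position, the
cumulative intensity distribution tracks the identity line (1/8, 2/8,
...) to within ~0.03 — the profile reads back the generating law.

A `lysoprof` console command exposes each step
(`normalize`, `qc`, `call`, `tissue-groups`, `compare`, `proptest`,
`radial`, `radial-compare`, `simulate-proteome`, `simulate-cell`); see
`lysoprof --help`.

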