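# radialpolarity

Quantification of apical-basal epithelial polarity in fluorescence images of
breast acini (glandular organoids grown in 3D culture).

Apical-basal polarity — the asymmetric organization of epithelial cells
around a lumen — is one of the first tissue features lost during carcinoma
initiation, which makes it a useful architectural readout for cancer-risk
and chemoprevention studies. The classic readout is visual scoring of
marker localization at the microscope: slow, subjective, and low
throughput. `radialpolarity` replaces it with an objective per-acinus
index computed from two image channels per field of view: a nuclear stain
(DAPI/Hoechst) used to find the acini, and a polarity-marker stain (e.g.
ZO-1, cortical actin, β4-integrin) whose radial distribution is measured.

## Method

For each field:

1. **Segmentation** — the nuclear channel is smoothed with a 3×3 mean
   filter, binarized with global Otsu thresholding, morphologically
   cleaned (opening + closing, hole filling), and touching acini are split
   by a watershed on the Euclidean distance transform. The resulting ROIs
   are dilated by a few pixels because the true membrane edge lies outside
   the nuclear-stain footprint.
2. **Filtering** — acini are excluded if they touch the image border, fall
   outside a size range, or are out of focus. Focus is measured per acinus
   with WAVR, the ratio of detail- to approximation-subband energy of a
   single-level Daubechies-6 wavelet transform; low WAVR means defocus. The
   cutoff can be fixed or chosen from the data (per-class normal fits and
   their equal-density intersection).
3. **Terracing** — each ROI's internal distance map is treated as a
   mountain (edges low, center high) and cut into *n* concentric terraces
   of equal height range; terrace 1 is the center (radius 0), terrace *n*
   the periphery (radius 1). A fixed *n* makes acini of different sizes
   comparable.
4. **Radial profile and RP index** — the mean polarity-marker intensity of
   each terrace is divided by the whole-acinus mean, giving a staining-
   independent profile RP₁..RPₙ. The profile collapses to the signed
   radial-polarity index

   RP = ± Σᵢ |1 − RPᵢ|,

   positive for descending profiles (marker concentrated at the center:
   apical) and negative for ascending ones (peripheral: basal); the sign
   comes from the least-squares slope of RPᵢ against normalized radius.
   Flat profiles score near 0.
5. **Statistics** — per-condition means and a pooled-variance Student's
   t-test on RP indexes compare treatment groups.

A synthetic-image generator renders fields of acini with known phenotype
(apical / basal / nonpolar), defocus and noise, together with ground
truth, so the whole pipeline is testable without microscope data. For
blind visual scoring, crops of all retained acini can be exported in
seeded random order with the condition labels kept in a separate key file.

## Worked example

Simulate a two-condition dataset (three fields each of apically polarized
and nonpolar acini) and analyze it:

```sh
$ radialpolarity simulate ds --seed 1
wrote 48 simulated acini under ds
$ printf 'wavr_cutoff: 0.0\nn_terraces: 8\n' > run.yaml
$ radialpolarity run ds out --config run.yaml
analyzed 6 fields, 48 acini (48 retained)
$ cat out/summary.csv
condition,n_acini,mean_rp,sd_rp,sem_rp
nonpolar,24,0.045439921384249904,0.07498935634860115,0.015307138266150929
polarized,24,1.5644641565854105,0.12379119664498012,0.025268772202394516
$ cat out/comparisons.csv
group_a,group_b,t,df,p
nonpolar,polarized,-51.416501725883954,46.0,2.705156323544483e-42
```

The polarized condition averages RP ≈ +1.56 (strong central
concentration of the marker, positive = apical) while the nonpolar one
sits near 0 (flat profiles); the t-test separates the groups decisively.
`out/results.csv` lists every acinus with its RP₁..RP₈ profile, signed
index, WAVR value and exclusion reason; `out/overlays/` holds the
polarity images annotated with ROI contours (green = retained, red =
excluded) and RP indexes. Against the simulator's ground truth:

```sh
$ radialpolarity evaluate out/results.csv ds/ground_truth.csv
{
  "detection_sensitivity": 1.0,
  "sign_accuracy_apical": 1.0,
  ...
}
```

The blur cutoff was set to 0 above because the example contains no
defocused acini; on real datasets use a calibrated value or
`wavr_cutoff: auto`.

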