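# smoothnet

Gaussian spatial smoothing is a standard fMRI preprocessing step, but for
ROI-level functional brain networks it is not harmless: because link weights
are Pearson correlations of ROI-averaged BOLD signals and networks are
thresholded to a fixed link density, anything that inflates some correlations
more than others reshuffles which links survive. `smoothnet` implements the
full analysis chain needed to quantify this — voxel-level smoothing, ROI
aggregation, correlation-network construction, density thresholding, and the
node/network metrics used to describe the distortion — together with a
synthetic cohort generator, so the whole experiment runs end-to-end without
any imaging data. It is aimed at researchers who build ROI-level connectomes
and want to know what their smoothing kernel does to them.

## The model

Smoothing replaces each voxel series by a normalized kernel average,

    x_i <- sum_j G_i(j) x_j / sum_j G_i(j),

with `G` an isotropic Gaussian of full width at half maximum FWHM
(σ = FWHM / (2√(2 ln 2))), evaluated in millimetre space and truncated at 4σ.
ROI signals are unweighted member means, `X_I = (1/N_I) Σ_{i∈I} x_i`; link
weights are Pearson correlations `A_IJ = corr(X_I, X_J)` with `A_II = 0`;
thresholding to density `d` keeps exactly `round(d·R(R−1)/2)` of the
strongest links as an unweighted graph. Node metrics are degree, competition
degree rank, and eigenvector centrality (power iteration on the binary
adjacency); network structure is summarized by the largest connected
component (LCC) and its cross-subject membership fraction. Correlations are
averaged and differenced on the Fisher-Z scale, `Z = arctanh(r)`.

The synthetic cohort places `R` mirrored contiguous ROIs of log-normal sizes
on a two-hemisphere voxel lattice, draws latent ROI signals whose
correlations decay as `exp(−distance/λ)` with a homotopic (mirror-pair)
bonus, perturbs the correlation target per subject, and adds independent
Gaussian voxel noise.

## Worked example

```sh
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_run_smoothing_sweep.py --seed 0
python analysis/03_summarize_effects.py
```

The sweep prints (seed 0, 13 subjects, 96 ROIs, 212 timepoints):

```
 fwhm_mm  mean_degree  degree_eigenvector_r  lcc_dispersion  roi_size_degree_change_r  delta_z_shortest_bin  delta_z_longest_bin
     0.0          9.5              0.909325        0.122658                       NaN              0.000000             0.000000
     5.0          9.5              0.922787        0.097880                 -0.393549              0.270766             0.017350
     8.0          9.5              0.917114        0.082840                 -0.507688              0.593570             0.036541
    12.0          9.5              0.902420        0.093565                 -0.530597              0.869576             0.055424
```

Reading the columns: the mean degree is pinned at `2·456/96 = 9.5` because
the 10%-density threshold fixes the link count, so smoothing can only
*redistribute* degree. The negative ROI-size/degree-change correlations show
where it goes: small ROIs gain links and large ROIs lose them, increasingly
so at wider kernels. The Fisher-Z weight change in the shortest distance bin
dwarfs that in the longest bin (0.27 vs 0.02 at FWHM 5 mm, 0.87 vs 0.06 at
12 mm): smoothing amplifies short-range connectivity most. Degree and
eigenvector centrality stay strongly correlated (r ≈ 0.90) at every width,
and the LCC-membership dispersion across subjects drops below its unsmoothed
value once any smoothing is applied — subjects agree more about the network
core, at the price of a systematically short-range one.

The same stages are scriptable from a shell (`smoothnet simulate|smooth|
network|metrics|sweep`), including NIfTI input for real volumes plus a label
atlas.

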