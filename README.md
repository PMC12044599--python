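# denoisebench

Multi-metric benchmarking of resting-state fMRI denoising pipelines — with
a built-in synthetic cohort, so the whole comparison runs end to end with
no external data.

## The problem

After standard preprocessing, rs-fMRI data still carry motion, physiological
and scanner artifacts.  Many confound-regression strategies exist — motion
parameter expansions (6/12/24 MPs), tissue mean signals (WM, CSF, global
signal), anatomical principal components (aCompCor), ICA-based automatic
motion-artifact removal — and they disagree: strategies that remove the most
noise also remove the most signal.  `denoisebench` applies ten processing
conditions (minimal preprocessing + nine denoising pipelines) in parallel to
the same data and scores each on eight quality metrics spanning three
sensitivities:

- **noise removal** — FD–DVARS correlation (residual motion),
  high-frequency wavelet-coherence content destroyed by denoising;
- **network identifiability** — signed-Louvain modularity *Q* of the
  Pearson connectome, and the functional connectivity contrast
  FCC = *Z* of the Wilcoxon rank-sum test separating within-network from
  between-network edges (time-domain and low-frequency wavelet variants);
- **signal preservation** — fraction of 0.01–0.1 Hz ROI power retained,
  and temporal-degrees-of-freedom loss (regressors removed / T).

FD–DVARS and tDOF loss are inverted (1 − |x|), every metric is z-scored
over the pooled subject × pipeline panel, and the **summary performance
index** is the mean of the three category means.  Pipelines are compared
with Kruskal–Wallis tests and Dunn-type post hocs at a family-wise
threshold of 0.005 (Bonferroni over the eight metric families).

Because real rs-fMRI has no noise-free ground truth, the package also
simulates cohorts with known structure: phantom anatomy, random-walk head
motion with optional spikes, structured noise (drift, aliased
respiratory/cardiac oscillations, a GM-dominant global fluctuation, white
system noise, motion-coupled intensity artifacts) and a planted
band-limited network signal with controlled within-network correlation.
See `docs/methods.md` for the model and every default.

## Worked example

`examples/denoise_single_subject.py` simulates one high-motion subject,
preprocesses it and compares two pipelines:

```
mean FD = 0.274 mm
pipeline         FD-DVARS r  tDOF lost
baseline              0.567      0.0%
mp24                 -0.026     12.0%
wm+csf+gs             0.626      1.5%
lower |r| = less residual motion; mp24 buys it with 12% of the tDOF
```

Frame-to-frame image changes track head motion strongly in the baseline
(r = 0.57); regressing the 24 motion-parameter terms removes that coupling
almost completely (|r| = 0.03) at the price of 24 of the 200 temporal
degrees of freedom, while the 3-regressor tissue pipeline leaves it in
place — the kind of trade-off the summary index is built to arbitrate.

`examples/full_benchmark.py` runs the whole comparison on a 6-subject
synthetic cohort:

```
median summary performance index (z-score units):
  acompcor+gs      +0.227
  wm+csf+gs        +0.139
  aroma+acompcor   +0.082
  aroma+gs         +0.053
  ...
  aroma            -0.300
```

Pipelines combining tissue-mean/aCompCor regression with global-signal
regression give the best compromise between artifact removal and
information preservation on these cohorts; ICA-based removal pays heavily
on the signal-sensitive metrics.  The other examples
(`simulate_cohort.py`, `coherence_bands.py`) show the generator's motion
profiles and the band-resolved wavelet-coherence estimator.

There is also a stage-wise CLI over a work directory
(`denoisebench run-all --out work/ --subjects 5 --seed 1`, or the
individual `simulate / preprocess / denoise / connectivity / metrics /
score / report` stages, each resumable from the previous stage's files).

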