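# coloct

Quantitative analysis of endoscopic optical coherence tomography (OCT)
imaging of the murine colon, built for longitudinal colitis studies
(e.g. the DSS model: baseline at day 0, inflammation peak around day 9,
recovery by day 24).

A side-viewing fiber probe rotates inside a transparent sheath (one B-scan
per revolution) while being pulled back along the colon, sampling the
lumen wall on a helix. `coloct` takes the resulting A-scan stream or
B-scan stack and produces the two imaging biomarkers that track
inflammation, with the statistics to compare groups over time:

* **wall thickness** — the colon wall (colonic mucosa, muscularis mucosa,
  submucosa, muscularis propria) thickens with inflammatory swelling;
* **attenuation coefficient μ<sub>A</sub> = μ<sub>s</sub> + μ<sub>a</sub>** —
  the depth-decay rate of backscattered intensity per Beer–Lambert,
  *I(z) = I₀ e^(−2 μ_A z)* (the factor 2 is the round trip), which drops
  in inflamed tissue as immune-cell infiltration changes the refractive
  index contrast. μ_A is estimated per layer by ordinary least squares of
  ln *I* on physical depth after averaging A-scans in linear intensity.

The pipeline stages (each usable as a library call or a CLI subcommand):

1. **reconstruction** — frame the helical A-scan stream into B-scans,
   log-compress, render circular (polar) views, extract en-face slices;
2. **segmentation** — Canny edge detection, hole filling, morphological
   closing, sheath removal, largest-component wall masking, and
   flattening (per-A-line alignment of the wall surface to row 0, which
   also suppresses motion artifacts);
3. **quantification** — thickness maps sampled at 10 pullback locations,
   per-layer Beer–Lambert fits, percent change versus the day-0 baseline;
4. **stats** — two-way (group × day) ANOVA with Type II sums of squares;
   the disease signal is the group × day *interaction*;
5. **synthetic phantom** — a fully ground-truthed generator of layered
   cylindrical colon volumes (Beer–Lambert decay, multiplicative speckle,
   sheath rings, detachment gaps, motion jitter, crypt texture, and a
   configurable colitis effect), so every stage is validated end to end
   without instrument data.

## Worked example

Simulate a full two-group longitudinal study (3 mice per group, days 0, 9
and 24, challenged mice thickened ×1.5 with attenuation ×0.7 at day 9),
segment and quantify every volume, and run the statistics:

```bash
coloct run --seed 5 --out out/
coloct report --quant out/quant.csv --response thickness_um --out out/report
```

The second command prints

```
group x day interaction: p = 3.752e-05 ***
```

`out/quant.csv` holds one row per (mouse, day, pullback bin, layer):

```
mouse,group,day,bin,bin_mm,layer,mu_A_mm,thickness_um,pct_change
unch1,unchallenged,0,0,0.6,colonic_mucosa,2.81379,409.42,1.68588
...
```

and `out/summary.csv` the box-plot-ready group × day summaries; for the
mucosa, thickness (µm) behaves as designed — the challenged group swells
at day 9 and recovers:

```
       group  day          layer       mean        sd   n
  challenged    0 colonic_mucosa 397.161836 14.814667  30
  challenged    9 colonic_mucosa 586.956522 29.450296  30
  challenged   24 colonic_mucosa 389.492754 35.977996  30
unchallenged    0 colonic_mucosa 392.391304 14.775785  30
unchallenged    9 colonic_mucosa 382.246377 12.323617  30
unchallenged   24 colonic_mucosa 380.434783 17.544717  30
```

The ×1.5 day-9 effect on the challenged group (587/397 ≈ 1.48) is
recovered through the full image pipeline, and the interaction p-value
flags it at the *** (p ≤ 0.001) level. Other subcommands: `simulate`,
`reconstruct`, `segment`, `quantify` operate on single volumes; see
`coloct --help`.

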