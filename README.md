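# facesym

Marker-based quantification of facial movement asymmetry from 2D video
trajectories.

Facial movement symmetry is a key indicator of neuromuscular function;
asymmetric execution of facial exercises accompanies facial-nerve
dysfunction, craniofacial surgery and neurological disease, and its
clinical assessment is traditionally visual and subjective. `facesym`
implements an objective alternative for marker-based video recordings:
given per-frame 2D trajectories of fiducial facial markers and the two
eye centroids, it quantifies how symmetrically an exercise (eyebrow
raising, smiling) was executed and tests whether dynamic movement
descriptors separate symmetric (S) from asymmetric (AS) executions.
It is aimed at researchers in facial-motion analysis and rehabilitation
who work with trajectory data extracted from video, not at clinical
decision making.

Because clinical video datasets of this kind are private, the package
ships a seeded synthetic-cohort simulator that emulates 50 fps marker
streams with controllable left/right amplitude asymmetry, phase lag,
head wobble, detection jitter, single-frame dropouts and eye-centroid
jump artifacts. All validation is performed against this simulator's
ground truth.

## Method

For each frame *t*, the facial symmetry axis is the perpendicular
bisector of the segment joining the eye centroids, in general line form
*a(t)x + b(t)y + c(t) = 0* (unit-normalized, a ≥ 0). The perpendicular
distance of marker *i* to the axis is

    d_i(t) = |a(t)·x_i(t) + b(t)·y_i(t) + c(t)| / sqrt(a²(t) + b²(t)).

Two features are computed per frame for the exercise's homologous marker
pair (markers 00/01 above the eyebrows for eyebrow raising, 10/11 at the
mouth corners for smiling):

* **VertDist(t) = |y_i(t) − y_j(t)|** — absolute vertical inter-marker
  distance (pixels);
* **Ratio(t) = d_L(t) / d_R(t)** — quotient of the left and right
  members' axis distances (1 = lateral symmetry).

Eye-centroid tracks are first cleaned: single-frame detection gaps are
linearly interpolated, and centroid jumps exceeding 10% of the per-frame
interocular distance (IPD) are replaced by the mean of the neighboring
frames.

Each feature series is normalized per recording with a robust z-score,
(x − median) / (1.4826·MAD), and summarized by six dispersion
descriptors: STD, MAD and IQR of the normalized series, and dSTD, dMAD,
dIQR of its first derivative (frame-to-frame velocity variability).
Groups are compared per descriptor with Welch's *t*-test
(Welch–Satterthwaite df), bias-corrected Hedges' *g* (computed as
AS − S, so descriptors higher in S yield negative *g*), Shapiro–Wilk and
Levene assumption checks, and univariate ROC analysis with the Youden
operating point (J = sensitivity + specificity − 1). Rater-panel
agreement on the S/AS labels is measured with Fleiss' kappa and the
2-of-3 majority rule.

## Worked example

`examples/04_group_statistics.py` simulates a smiling cohort of 50
symmetric and 21 asymmetric executions (right side at half amplitude
with a 2-frame lag) and runs the full pipeline:

```
descriptor              t     df         p       g  sig
Ratio_dSTD        -16.009   58.5   4.9e-23  -3.430  *
Ratio_dMAD        -12.939   52.8   5.3e-18  -2.893  *
Ratio_dIQR        -12.885   52.2   7.5e-18  -2.892  *
...
VertDist_dSTD     -33.321   69.0   2.9e-44  -6.327  *
VertDist_dMAD     -32.401   68.3   3.5e-43  -6.334  *
VertDist_dIQR     -31.983   68.3   7.7e-43  -6.246  *
...
top 3 descriptors by AUC:
  VertDist_dMAD: AUC=1.000, Youden J=1.000 at threshold 0.897
  VertDist_dSTD: AUC=1.000, Youden J=1.000 at threshold 0.943
  VertDist_dIQR: AUC=1.000, Youden J=1.000 at threshold 1.204
```

Every derivative-based descriptor is significantly **lower** in the
asymmetric group (negative *t* and *g*): attenuated, lagged motion shows
less relative frame-to-frame velocity variability once each recording is
robustly normalized, and the derivative descriptors dominate the ROC
ranking. The other examples cover cohort simulation, axis/feature
extraction, artifact filtering against injected ground truth, and
rater agreement; each prints a short self-explaining summary.

The same chain is available as a thin CLI:

```sh
facesym simulate --exercise smiling --n-s 50 --n-as 21 --rho 0.5 --seed 7 --out-dir cohort/
facesym run --in-dir cohort/ --out-dir results/
```

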