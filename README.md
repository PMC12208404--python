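# paleogait

**What would change in hip muscle recruitment if a modern human walked on an
australopithecine-shaped hip?**

`paleogait` is a desk-scale musculoskeletal gait-simulation package for
comparative questions of exactly that form.  It holds a walker's size,
kinematics and external kinetics fixed and swaps only the shape of the hip
(pelvis and proximal femur) between a modern-human-like form and an
australopithecine-like form — relatively broad biacetabular spacing, low
weakly-wrapped iliac blades, an anteroposteriorly compressed pelvis, and a
modestly longer femoral neck — then asks how the muscle activations and hip
joint reaction forces differ.  It is aimed at biomechanists and
paleoanthropologists who want a fully inspectable, fully synthetic rig for
this class of experiment: every input is generated by seeded code, and every
stage is testable against closed-form oracles.

## The pipeline

1. **Synthetic cohort and gait** (`paleogait.synthetic`) — ten adults (five
   female, five male), three walking passes each: 52-marker trajectories,
   two force-plate records and gait events, built so that kinematics and
   kinetics are mutually consistent by construction.
2. **Shape machinery** (`paleogait.morphology`) — thin-plate-spline landmark
   warps (63-landmark pelvis schema), iterative-closest-point rigid
   alignment, staged coherent-point-drift correspondence (λ=1;
   β = 50, 30, 10, 8), reflect-relabel-average asymmetry reduction, the
   hybrid femur (fossil-shaped proximal 20 %, human distal end, TPS-smoothed
   shaft; 237/2500 control vertices), joint-center-preserving scaling and
   anterior-pelvic-plane orientation (sacral slope ≈ 30°).
3. **Musculoskeletal model** (`paleogait.model`) — nine lower-body rigid
   segments plus a lumped trunk, ball-joint hips, hinge knees/ankles, and
   160 muscle elements whose hip attachment geometry is parametric in the
   shape variant (12-element gluteal fans per side).  Moment arms by the
   tendon-excursion relation r = −∂L/∂θ.
4. **Inverse dynamics** (`paleogait.dynamics`) — marker-cluster pose
   fitting, zero-lag filtering, recursive Newton–Euler joint loads, and a
   whole-body residual wrench that is reported, never hidden.
5. **Muscle redundancy** (`paleogait.redundancy`) — frame-wise

       min Σᵢ aᵢ³   subject to   B a = τ,  a ≥ 0,

   the cubic recruitment criterion over activations a = F/F_max, solved by a
   damped-Newton dual method to ~1e-9 moment-balance residuals.
6. **Curve statistics** (`paleogait.stats`) — 101-node stride
   normalization, element-to-muscle aggregation, body-weight normalization,
   left-to-pseudo-right mirroring, and permutation SPM: a node-wise
   repeated-measures ANOVA (10 subjects × 2 hip forms × 3 trials) whose
   critical threshold is the permutation distribution of the field maximum
   under within-subject condition flips.

The driver (`paleogait.pipeline.run_pipeline`) computes kinematics and
external joint loads **once per trial** and feeds the identical inputs to
both hip variants — the comparison isolates shape, nothing else.

## Worked example

```python
from paleogait import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=1))
curves = result["curves"]

for group in ("gluteus_medius", "gluteus_minimus", "gluteus_maximus"):
    h = curves.curve_matrix(f"{group}_activation", "human_like").to_numpy()[:, :61].mean()
    a = curves.curve_matrix(f"{group}_activation", "australopith_like").to_numpy()[:, :61].mean()
    print(f"{group:16s} human {h:.3f}  australopith {a:.3f}")
```

On the default cohort this prints:

```
gluteus_medius   human 0.218  australopith 0.231
gluteus_minimus  human 0.186  australopith 0.265
gluteus_maximus  human 0.154  australopith 0.115
```

Mean-stance activations are dimensionless fractions of maximum muscle
strength, averaged over the first 60 % of the stride (stance).  The
australopith-shaped hip recruits the abductors (medius, minimus) harder —
its abductor fan is bunched toward the coronal plane, so the anterior
fibers that a human hip uses for combined abduction/internal rotation are
missing — while gluteus maximus, whose extension lever shortens with the
anteroposterior compression of the pelvis, hands its work to the hamstrings
and posterior abductor fibers and ends up *less* active.  The mean-stance
vertical hip joint reaction rises from ≈ 5.8 to ≈ 7.1 body weights, and the
direction-of-travel reaction during propulsion drops.  SPM marks the
medius, minimus and maximus condition effects significant with
suprathreshold clusters in early and mid stance (`result["spm"]`).

A command-line interface mirrors the library
(`paleogait generate / morph / model / dynamics / solve / compare / run /
report`); `paleogait run --seed 1 --out out/` writes trials, tidy curve
tables, SPM summaries and a hash-stamped run manifest.

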