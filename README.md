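# radbed

Radiobiological fractionation and DVH analysis for simultaneous-integrated-boost
(SIB) radiotherapy: isoeffective schedule calculation from the linear-quadratic
model, conversion of dose-volume histograms (DVHs) and dose-volume constraints
to the 2 Gy-per-fraction scale (NTD2 / EQD2), and Poisson-TCP / LKB-NTCP /
therapeutic-gain evaluation from DVHs.

## Who this is for

Medical physicists and radiotherapy researchers who need to

- re-prescribe nested target volumes so an SIB plan delivers, in one shared
  fraction number, the same biologically effective dose (BED) each target would
  have received under its conventional fractionation;
- convert organ-at-risk (OAR) dose-volume constraints, stated at 2 Gy per
  fraction, to hypo- or hyper-fractionated schedules;
- compare treatment plans exported from different planning systems on the
  common NTD2 scale and rank them by TCP, NTCP and the therapeutic gain P+.

## The model

Cell survival follows the linear-quadratic model: for total dose *D* in
fractions of size *d*,

    ln sf = −α·D·(1 + d/(α/β)) = −α·BED,     BED = D·(1 + d/(α/β)).

Schedules with equal BED are isoeffective. Given a fixed fraction number *n*
(set by the reference target) and a target BED, the isoeffective dose per
fraction is the positive root of `n·d·(1 + d/(α/β)) = BED`:

    d = (α/β)/2 · (−1 + √(1 + 4·BED / (n·α/β))).

Per-bin NTD2 conversion uses `NTD2 = D·(α/β + d)/(α/β + 2)` with
`d = D/n`. Tumor control is Poisson, `TCP = exp(−N*·Σᵢ vᵢ·sfᵢ)` (clonogens
partitioned over DVH bins); normal-tissue complications use the
Lyman-Kutcher-Burman probit on the NTD2-corrected DVH after effective-volume
reduction `v_eff = Σᵢ vᵢ·(NTD2ᵢ/NTD2max)^(1/n)` with
`TD50(v) = TD50(1)·v^(−n)`; the therapeutic gain is
`P+ = TCP·∏ⱼ(1 − NTCPⱼ)` (difference form switchable).

## Worked example

The classic prostate + pelvic-nodes case: the prostate (reference target)
keeps 80 Gy in 40 fractions of 2 Gy; the nodes were conventionally prescribed
50 Gy at 2 Gy per fraction; α/β = 1.5 Gy for both targets.

```sh
radbed isobed --target prostate:80:2:1.5 --target nodes:50:2:1.5 \
       --reference-target prostate
```

prints

```text
label	total_gy	dose_per_fraction_gy	n_fractions	bed_gy
prostate (reference)	80.0000	2.0000	40	186.6667
nodes	58.8819	1.4720	40	116.6667

organ	volume	volume_unit	endpoint	alpha_beta_gy	limit_2gy_gy	limit_converted_gy	dose_per_fraction_gy	note
rectum	0.3000	fraction	grade>=2 proctitis	3.0000	70.0000	72.6650	1.8166
...
```

Reading: delivering the nodes in the prostate's 40 fractions requires
1.4720 Gy per fraction (58.88 Gy total) to keep their BED at
116.67 Gy — the same BED as 50 Gy at 2 Gy/fx. The constraint table converts
each 2 Gy/fx OAR limit to the 40-fraction schedule the same way (e.g. the
rectum 70 Gy limit relaxes to 72.67 Gy because each of the 40 fractions is
smaller than 2 Gy at that dose level). Shipped constraint values are
illustrative placeholders, not clinical recommendations.

The same computation via the API:

```python
import radbed as rb

rx = rb.SIBPrescription(targets=(
    rb.TargetPrescription("prostate", rb.Schedule(80, 2, 40), 1.5),
    rb.TargetPrescription("nodes", rb.Schedule(50, 2, 25), 1.5),
))
for label, sched in rb.sib_prescription(rx):
    print(label, round(sched.total_dose, 4), round(sched.dose_per_fraction, 4))
# prostate 80.0 2.0
# nodes 58.8819 1.472
```

DVH workflows (`radbed dvh-stats`, `ntd2`, `tcp-ntcp`, `compare`) operate on
DVH export files; `radbed gen-fixtures --out DIR` writes fully synthetic
example patients in the canonical format and in three emulated
planning-system dialects. See `docs/methods.md` for the model details and
conventions.

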