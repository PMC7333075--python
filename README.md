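# zonescreen

Event-zone time-series clustering and screening evaluation for virtual
driving test (VDT) telemetry.

State licensing agencies can pre-screen license applicants with a
self-directed simulator drive before the on-road examination (ORE, an
integer infraction score where >= 26 fails).  The screening question: can
~8 minutes of multichannel telemetry — pedals, steering, lane offset, pose,
speed at ~10 Hz — predict who will fail the road test?  `zonescreen`
implements two featurizations of a drive and the metric suite to compare
them as screens:

* **Engineered variables** — a fixed catalog of 67 per-drive summaries of
  speed management, limit adherence, control inputs and rule-based
  infractions (the resource-intensive standard approach).
* **Event-zone time-series clustering** — the route is pre-partitioned into
  behaviour-eliciting *event zones* (crosswalks, school zones,
  intersections, a rear-end conflict, ...).  Each drive's per-zone
  subinterval of (lane offset, throttle, brake, steering) is compared to
  all others with dynamic time warping, clustered with k-medoids (k = 8,
  20 restarts, squared-dissimilarity inertia), and the drive is represented
  by its dissimilarity to every medoid — a soft-clustering vector of
  k x n_zones features (1328 at full scale) requiring no manual feature
  design.

Classifiers (cross-validated logistic threshold sweep; RBF-SVM dyadic grid)
are scored with the screening-oriented suite: accuracy, fail rate,
false-alarm rate, ratio of false alarms, risk ratio of ORE failure given a
screen failure with Katz 95% CI, TPR/FPR and trapezoidal ROC/AUC.  Because
published summary tables print rounded percentages over a known cohort
(N = 4308, 1096 failures), the package can also invert a table row back to
its unique integer confusion matrix by exhaustive search and recompute
every derived statistic exactly.

The original pilot cohort is not public, so the package ships a synthetic
drive simulator: routes with typed event zones, per-zone behaviour
*archetypes* (e.g. crosswalk: full stop / slow yield / no yield) drawn
according to a latent driver skill, time-warp jitter so sequences have
unequal lengths, and ORE scores coupled to skill and executed infractions.
Everything downstream is exercised against this generator, including
recovery of planted cluster structure and a signal-versus-null screening
study.  See `docs/methods.md` for the model details and what the synthetic
results do and do not show.

## Worked example

```python
from zonescreen.screen_eval import (ConfusionMatrix, reconstruct_confusion,
                                    screening_metrics)

# invert a published table row (cohort N=4308, 1096 ORE failures) from its
# rounded metrics to the unique integer confusion matrix
cm = reconstruct_confusion(4308, 1096,
                           {"tpr": 10.0, "fpr": 1.3,
                            "ratio_false_alarms": 27.2})
print((cm.FF, cm.FP, cm.PF, cm.PP))
m = screening_metrics(cm)
print(f"RR {m.rr:.3f} (95% CI {m.rr_ci[0]:.3f}-{m.rr_ci[1]:.3f}), "
      f"accuracy {100*m.accuracy:.1f}%")
```

prints

```
(110, 41, 986, 3171)
RR 3.071 (95% CI 2.747-3.434), accuracy 76.2%
```

i.e. drivers failed by this screen were 3.07 times as likely to fail the
road exam as drivers it passed, at 76.2% overall accuracy.

A full synthetic run, from simulation through clustering to evaluation:

```bash
zonescreen run --config run.yaml     # or: zonescreen simulate / extract /
                                     # cluster / featurize-variables /
                                     # evaluate for the individual stages
```

with a `run.yaml` such as

```yaml
n_drivers: 200
n_env: 2
total_zones: 12
route_length: 650.0
zone_scale: 0.4
k: 8
restarts: 20
seed: 7
out_dir: runs/demo
```

which writes replays, the cohort table, per-zone cluster models with
per-cluster ORE summaries, the membership and variables feature CSVs, the
threshold-sweep metrics, ROC points and a JSON run report.

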