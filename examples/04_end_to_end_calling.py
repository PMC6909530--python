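"""Train the CNN on one chromosome and call deletions on another.

A compact version of the full workflow: simulate a training chromosome with
known deletions, train the window classifier, then scan an independent test
chromosome — classify every 50 bp window, merge hits into candidates, screen
and refine them by clustering — and score the calls against the truth.
Takes a couple of minutes on one CPU.
"""

import delcall as dc

lib = dc.LibraryModel(coverage=24)

train_dels = dc.random_deletions(10, 300_000, (200, 2500), seed=31,
                                 zygosity="mixed", chrom="chr_train")
train_scene = dc.simulate_scene(300_000, train_dels, lib, seed=31,
                                chrom="chr_train")
model, history = dc.train_on_scene(train_scene, epochs=10, seed=0)
print(f"trained on {len(train_dels)} known deletions; "
      f"final training accuracy {history.train_accuracy[-1]:.3f}")

test_dels = dc.random_deletions(8, 300_000, (200, 2500), seed=32,
                                zygosity="mixed", chrom="chr_test")
test_scene = dc.simulate_scene(300_000, test_dels, lib, seed=32,
                               chrom="chr_test")
calls = dc.call_deletions(model, test_scene.reads, "chr_test", test_scene.length)

print(f"\n{'truth':>22}  {'call':>22}  prob")
report = dc.evaluate(calls, test_scene.deletions)
for d in test_scene.deletions:
    match = next((c for c in calls
                  if min(c.end, d.end) - max(c.start, d.start) > 0), None)
    t = f"{d.start}-{d.end} ({d.zygosity[:3]})"
    c = f"{match.start}-{match.end}" if match else "MISSED"
    p = f"{match.probability:.2f}" if match else ""
    print(f"{t:>22}  {c:>22}  {p}")
print(f"\nprecision {report.precision:.2f}  sensitivity {report.sensitivity:.2f}"
      f"  F-score {report.f_score:.2f}")
print("breakpoint distances (bp):", report.breakpoint_distances)
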