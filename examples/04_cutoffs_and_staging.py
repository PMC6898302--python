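"""Diagnostic cutoffs at fixed specificity, classification, and HPA staging.

Computes 95%/99%-specificity cutoffs from simulated normal eyes (on the
linear scale for dB parameters), classifies the glaucoma eyes, and scores
the staging agreement between NFL_MD and VF_MD with the F1 statistic.
"""

import nflmd

cfg = nflmd.CohortConfig(n_normal=120, n_ppg=0, n_pg=120, seed=7)
visits, _ = nflmd.simulate_cohort(cfg)
scored = nflmd.score_frame(visits)
eye = scored.groupby("eye_id").agg(
    group=("group", "first"), vf_md=("vf_md", "mean"),
    nfl_md=("nfl_md_db", "mean")).reset_index()

normals = eye[eye["group"] == "normal"]
cut = nflmd.specificity_cutoffs(normals["nfl_md"], "nfl_md")
print(f"NFL_MD cutoffs ({cut.scale_used}): "
      f"95% spec = {cut.cutoff95:.2f} dB, 99% spec = {cut.cutoff99:.2f} dB")

pg = eye[eye["group"] == "pg"]
labels = pg["nfl_md"].map(lambda v: nflmd.classify_eye(v, cut))
print("PG classification:", labels.value_counts().to_dict())

# staging agreement (stage 0-1 vs 2-3 at the -6 dB boundary)
truth = pg["vf_md"].map(nflmd.binarize_stage)
pred = pg["nfl_md"].map(nflmd.binarize_stage)
tp = int(((truth == "stage0_1") & (pred == "stage0_1")).sum())
fn = int(((truth == "stage0_1") & (pred == "stage2_3")).sum())
fp = int(((truth == "stage2_3") & (pred == "stage0_1")).sum())
tn = int(((truth == "stage2_3") & (pred == "stage2_3")).sum())
print(f"staging table tp={tp} fn={fn} fp={fp} tn={tn}, "
      f"F1 = {nflmd.staging_f1(tp, fn, fp, tn):.2f}")

# The published perimetric-glaucoma table (201, 14, 45, 29) gives F1 = 0.87.
print(f"reference-table F1 check: {nflmd.staging_f1(201, 14, 45, 29):.2f}")
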