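"""Train a miniature localization+segmentation cascade on phantoms.

Uses a deliberately small pool (12 phantoms) and short schedules so the
demo finishes in a few minutes on one CPU; the acceptance run uses 60
phantoms and longer training.  Printed Dice scores are overlap between
the restored automatic pericardium masks and the ground truth on two
held-out phantoms (1.0 = perfect).
"""

from pericfat import cascade, locnet, phantom, segnet

pool = phantom.phantom_pool(12, base_seed=100)
train, test = pool[:10], pool[10:]

loc_cfg = locnet.LocConfig.scaled_down(seed=0, epochs=16)
seg_cfg = segnet.SegConfig.scaled_down(seed=0, epochs=24)

print("training cascade (miniature profile)...")
casc = cascade.train_cascade(train, loc_cfg, seg_cfg)
print(f"localization final train loss: {casc.loc.log.train_loss[-1]:.3f}")
print(f"segmentation final train loss: {casc.seg.log.train_loss[-1]:.3f}")

ev = cascade.evaluate_cascade(test, casc)
print(ev.table.to_string(index=False))
print(f"median Dice on held-out phantoms: {ev.median_dice:.3f}")
print(f"median surface distance: {ev.median_surface_distance_mm:.2f} mm")
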