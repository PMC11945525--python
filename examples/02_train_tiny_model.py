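"""Overfit the tiny model on a handful of synthetic ribbons.

A quick CPU sanity run: 8 images at 96 px, 120 optimization steps.  The
printed Dice is computed on the training images themselves, so it shows the
model and loss can fit the data, not that they generalize.
"""

from stripseg import SyntheticConfig, TrainConfig, generate_sample, train, validate

cfg = SyntheticConfig(canvas_size=96, seed=11)
pairs = [(s.image, s.mask) for s in (generate_sample(cfg, seed=1000 + i) for i in range(8))]

tc = TrainConfig.tiny(seed=1, max_steps=120)
result = train(tc, pairs, val_every=40)
report = validate(result.model, pairs)

print(result.history.tail(3).to_string(index=False))
print(f"\ntraining-set Dice after {len(result.history)} steps: "
      f"{report.means['dice']:.3f}")
print("loss_total should fall well below its first-step value; Dice above "
      "~0.7 already indicates the ribbons are being localized.")
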