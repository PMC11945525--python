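"""Generate a small synthetic ribbon dataset and inspect its manifest.

The generator emulates the data regime the segmentation method targets:
long, curved, low-contrast strip structures on textured backgrounds with
compact distractor blobs of the same contrast.
"""

from pathlib import Path

from stripseg import SyntheticConfig, generate_dataset

out = Path("scratch_example_dataset")
cfg = SyntheticConfig(canvas_size=128, seed=7)
manifest = generate_dataset(12, cfg, out)

print(manifest.to_string(index=False))
print(
    f"\n{len(manifest)} image/mask pairs written to {out}/ "
    "(images/ and masks/ as 8-bit PNG).\n"
    "width_min/width_max bound each ribbon's sampled width profile in px; "
    "split assigns 70/15/15 train/val/test."
)
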