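"""Instantiate the four architectures and print their parameter budgets.

The recurrent models add convolutional-recurrent blocks (RC) and
spatial-transformer alignment (SARC) to a slim one-conv-per-level U-Net;
the SARC U-Net stays well under the 3D U-Net's budget.
"""

from sarc_unet.models import MODEL_NAMES, ModelSpec, build_model, count_parameters

counts = {}
for name in MODEL_NAMES:
    counts[name] = count_parameters(build_model(ModelSpec(name)))
    print(f"{name:10s} {counts[name]:>12,} parameters")

saving = (counts["unet3d"] - counts["sarc_unet"]) / counts["unet3d"]
print(f"\nSARC U-Net uses {saving:.0%} fewer parameters than the 3D U-Net "
      "while still modeling inter-slice context.")
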