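"""Render one synthetic leaf image and extract its 15-feature vector.

The features are nine colour-channel means (RGB / HSV / CIE Lab) and six
first-order gray-histogram texture statistics.
"""

from withervision import extract_features, render_leaf_image

wet = render_leaf_image(moisture=0.75, seed=3)
dry = render_leaf_image(moisture=0.42, seed=3)

for label, img in (("wet (w=0.75)", wet), ("dry (w=0.42)", dry)):
    fv = extract_features(img)
    print(f"{label}:")
    for name, value in fv.as_dict().items():
        print(f"  {name:7s} {value:10.4f}")
    print()

print("Wet leaves are brighter (higher L*, G) and rougher (higher delta, "
      "entropy e; lower uniformity U) than dry ones -- the structure the "
      "downstream calibration models exploit.")
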