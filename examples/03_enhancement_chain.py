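"""The training detail-image chain: bilateral -> BPDHE -> SVE -> guided filter.

The high-resolution training image is denoised and re-contrasted before the
detail (HR minus interpolated LR) is formed; the singular-value-equalized
detail is then guided-filtered with the raw detail as guide so that true
structure survives while its noise does not.
"""

import numpy as np

from mesr import (
    DegradationSpec,
    SartConfig,
    build_mesr_detail_image,
    default_shepp_logan,
    degrade,
    radon_forward,
    rasterize_ellipse_phantom,
    sart_reconstruct,
    upscale,
)
from mesr.tomography import add_projection_noise

phantom = rasterize_ellipse_phantom(default_shepp_logan(), 128)
angles = np.arange(64) * 180.0 / 64
noisy = add_projection_noise(radon_forward(phantom, angles), 0.01, 0)
y_h = sart_reconstruct(noisy, SartConfig(1.0, 15), 128).pixels

spec = DegradationSpec(scale=2, blur_sigma=1.0)
y_l = upscale(degrade(y_h, spec), spec)
details = build_mesr_detail_image(y_h, y_l)

raw = details.raw_detail


def describe(name, img):
    corr = np.corrcoef(img.ravel(), raw.ravel())[0, 1]
    print(f"  {name:18s} std {img.std():.4f}  corr. with raw detail {corr:+.3f}")


print("detail-image chain statistics (128^2 SART training image):")
describe("raw  (y_h - y_l)", raw)
describe("enhanced (y_h' - y_l)", details.enhanced_detail)
describe("equalized (SVE)", details.equalized_detail)
describe("guided (final)", details.guided_detail)
print("\nThe final detail keeps the raw detail's structure (high correlation)")
print("while the bilateral/BPDHE stages have altered its noise content;")
print("this image supplies the HR patches the dictionary learns to synthesize.")
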