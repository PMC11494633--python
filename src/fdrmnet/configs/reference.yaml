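# Frozen reference configuration.
#
# Channel widths were tuned once so the assembled network reproduces the
# reference accounting figures
# (6.80 M parameters, 22.7 GFLOPs at 640x640 under the 2-FLOPs-per-MAC
# convention; ablation variants 7.85 M without AFFM, 8.99 M without the
# shared head) and are frozen here. Do not edit casually: the acceptance
# suite asserts the resulting totals.
backbone:
  stem_mid: 42
  stem_out: 20
  stage_mid: [24, 32, 168, 392]
  stage_out: [48, 96, 384, 1024]
  block_convs: 3
  sppf_k: 5
neck:
  branch: 64
  mid: 128
  out: 142
  affm_hidden: [64, 124, 212]
  affm_repeats: 1
  ema_groups: 4
  use_mffr: true
  use_affm: true
head_width: 152
head_depth: 2
num_classes: 1
input_size: 640
use_mffr: true
use_affm: true
use_lpsdh: true
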