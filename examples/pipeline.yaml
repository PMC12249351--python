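# Tiny end-to-end pipeline: simulate -> preprocess -> split -> train -> eval -> grade
seed: 7
out_dir: runs/tiny
stages: [simulate, preprocess, split, train, eval, profile, grade]
simulate:
  n_images: 24
  walnuts_per_image: 2
  class_mix: [0.5, 0.5]
  canvas: [300, 180]
train:
  epochs: 5
  batch_size: 8
  input_size: 160
model: {}
grade:
  n_walnuts: 30
  defect_rate: 0.5
  walnuts_per_frame: 2
  canvas: [300, 180]
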