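{
  "axial_length_mm": 200.0,
  "body_semi_axes_mm": null,
  "body_shape": "cylindrical",
  "body_volume_l": 6.283185307179586,
  "cold_inserts": [],
  "cylinder_diameter_mm": 200.0,
  "kind": "uniform_cylinder",
  "name": "uniform20",
  "spheres": []
}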