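{
  "axial_length_mm": 194.0,
  "body_semi_axes_mm": [
    150.0,
    106.10329539459688
  ],
  "body_shape": "noncylindrical",
  "body_volume_l": 9.7,
  "cold_inserts": [
    {
      "center_xy_mm": [
        0.0,
        0.0
      ],
      "density_class": "lung",
      "diameter_mm": 50.0,
      "shape": "cylinder",
      "z_range_mm": null
    }
  ],
  "cylinder_diameter_mm": null,
  "kind": "torso_iq",
  "name": "iq_nema",
  "spheres": [
    {
      "center_mm": [
        57.2,
        0.0,
        0.0
      ],
      "inner_diameter_mm": 37.0,
      "wall_thickness_mm": 1.0
    },
    {
      "center_mm": [
        28.60000000000001,
        49.53665309646989,
        0.0
      ],
      "inner_diameter_mm": 28.0,
      "wall_thickness_mm": 1.0
    },
    {
      "center_mm": [
        -28.599999999999987,
        49.5366530964699,
        0.0
      ],
      "inner_diameter_mm": 22.0,
      "wall_thickness_mm": 1.0
    },
    {
      "center_mm": [
        -57.2,
        7.0049796911228604e-15,
        0.0
      ],
      "inner_diameter_mm": 17.0,
      "wall_thickness_mm": 1.0
    },
    {
      "center_mm": [
        -28.600000000000026,
        -49.53665309646988,
        0.0
      ],
      "inner_diameter_mm": 13.0,
      "wall_thickness_mm": 1.0
    },
    {
      "center_mm": [
        28.60000000000001,
        -49.53665309646989,
        0.0
      ],
      "inner_diameter_mm": 10.0,
      "wall_thickness_mm": 1.0
    }
  ]
}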