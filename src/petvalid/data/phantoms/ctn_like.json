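{
  "axial_length_mm": 190.0,
  "body_semi_axes_mm": [
    160.0,
    109.94255937269085
  ],
  "body_shape": "noncylindrical",
  "body_volume_l": 10.5,
  "cold_inserts": [
    {
      "center_xy_mm": [
        -65.0,
        35.0
      ],
      "density_class": "lung",
      "diameter_mm": 60.0,
      "shape": "cylinder",
      "z_range_mm": [
        25.0,
        95.0
      ]
    },
    {
      "center_xy_mm": [
        65.0,
        35.0
      ],
      "density_class": "lung",
      "diameter_mm": 60.0,
      "shape": "cylinder",
      "z_range_mm": [
        25.0,
        95.0
      ]
    }
  ],
  "cylinder_diameter_mm": null,
  "kind": "torso_iq",
  "name": "ctn_like",
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
    },
    {
      "center_mm": [
        49.5366530964699,
        28.599999999999998,
        0.0
      ],
      "inner_diameter_mm": 7.0,
      "wall_thickness_mm": 0.5
    }
  ]
}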