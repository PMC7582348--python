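{
  "comment": "Coarse backbone-dihedral region polygons (degrees). Wrap-around is handled by the reader; polygons may extend past 180.",
  "regions": [
    {
      "name": "alpha_favored",
      "class": "favored",
      "polygon": [[-100, -80], [-100, -5], [-30, -5], [-30, -80]]
    },
    {
      "name": "beta_favored",
      "class": "favored",
      "polygon": [[-180, 90], [-180, 195], [-45, 195], [-45, 90]]
    },
    {
      "name": "alpha_allowed",
      "class": "allowed",
      "polygon": [[-160, -110], [-160, 10], [-20, 10], [-20, -110]]
    },
    {
      "name": "beta_allowed",
      "class": "allowed",
      "polygon": [[-180, 60], [-180, 210], [-30, 210], [-30, 60]]
    },
    {
      "name": "left_alpha_allowed",
      "class": "allowed",
      "polygon": [[30, -10], [30, 80], [90, 80], [90, -10]]
    }
  ]
}
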