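{
  "charge.tsv": "c2b9e76cc3bf110847afc9f7dbca8f97ab8dc4e4ec9626876389e0d7bfcaf17a",
  "disorder_propensity_topidp.tsv": "7bfad8e2e1f3a5faa5769093328d29eb4ce66a9984e0650b856b0bd99af64111",
  "energy_matrix_synthetic.tsv": "8e911eaabf85d31be343b127609a87e001cecff4b126e1e882ea28ec0632638d",
  "flexibility_smith.tsv": "f989893fb97e6746d215a0549994144ffc8de5347574ab5743cc3d75c0469502",
  "hydrophobicity_kd.tsv": "e9704143b0ec33eabd168bf874155cbd03e730b85d34c7f15ea9efb56906b7e6",
  "packing_contacts.tsv": "e890c92ce2032e721098b910e786e337be03df8a19deb753d841db0a4cdbaa67"
}
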