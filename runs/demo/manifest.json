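{
  "config": {
    "fr_values": [
      0.0,
      10.0,
      20.0
    ],
    "post_rules": true,
    "scale": 0.2,
    "scenario": "unrelated",
    "seed": 11,
    "suite": [
      "c20t20n",
      "c20t20o",
      "c30t20n",
      "c30t20o"
    ]
  },
  "stages": {
    "analyze": {
      "outputs": {
        "library_fr0.tsv": "a81f3d2f7a5bd1ae58ba05d25f92f05035acf221c9069c0274545f76a64095f3",
        "library_fr10.tsv": "a8c5becc3ca1bd204953c28225b8645b76a1e4889dab46f7acd634da1c2d4ccf",
        "library_fr20.tsv": "f7f4ad9fde8de5fc96dbacacfdf72749662040d35f49e0dcb81b9779b2ad0d00",
        "origins_fr0.tsv": "efe44bf2f0fc20ea393113e349758982de266fc546f05eb3d1ee85cb0cf27a28",
        "origins_fr10.tsv": "a39e7a7a894f7f138597a8c0cd83e63fe11f3522075e761a3201010f83c73ea9",
        "origins_fr20.tsv": "ce4b6d8370c8196d4235e33ad359748cbf7e7b2fb17605c88fe2dd4325d7aab2"
      }
    },
    "evaluate": {
      "outputs": {
        "accuracy.tsv": "53001745c21fefae5a465b5d898afd236c3209559fc1cb497afb1c5c66abd8a3"
      }
    },
    "simulate": {
      "outputs": {
        "composition.tsv": "76381898a85b3d14fc41a2792200272da620b47652405678f549eaffa6f73eab",
        "panel.map": "e6facd314e48c38f3ca5e93485595970912c286ee7a47c3bdc2ce3e0eca849a6",
        "panel.ped": "a52385c302dbd92769f5c24e207b64c0bc723d1394fd3edc12193a74a7103a12",
        "panel.tsv": "f1846f92c5a9304da5ae2cf8ff71488ead87df931c245f8e3e03bdbf4c6c2899",
        "truth_origins.tsv": "bb2b03107401eb05247b2656430dc804d65321711db071ae4e56c776c5e3aa70"
      }
    }
  }
}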