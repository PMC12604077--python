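{
  "source": "Chemical shifts (ppm, TMS/DSS scale) and scalar couplings (Hz) transcribed from Govindaraju V, Young K, Maudsley AA. Proton NMR chemical shifts and coupling constants for brain metabolites. NMR Biomed 2000;13:129-153.",
  "notes": "Exchangeable NH/OH protons and couplings to 31P are omitted throughout. Equivalent proton groups that are uncoupled (singlets, N(CH3)3) are stored as one spin with an integer weight; methyl/methylene groups whose coupling partners matter (e.g. lactate CH3) are stored as explicit identical-shift spins. GSH and NAAG are deliberately omitted: both are large multi-moiety spin systems whose 3.4-3.7 ppm contribution is minor, and reduced models would misstate their multiplets. Choline CH2-CH2 fragments use a weighted two-spin reduction of the A2B2 system.",
  "omissions": {
    "GSH": "glutathione: three-moiety >10-proton system, omitted",
    "NAAG": "N-acetylaspartylglutamate: >10-proton system, omitted"
  },
  "metabolites": {
    "Gly": {
      "shifts_ppm": [3.548],
      "j_hz": [[0.0]],
      "weights": [2]
    },
    "mI": {
      "shifts_ppm": [3.5217, 4.0538, 3.5217, 3.6144, 3.269, 3.6144],
      "j_hz": [
        [0.0, 2.889, 0.0, 0.0, 0.0, 9.998],
        [2.889, 0.0, 2.889, 0.0, 0.0, 0.0],
        [0.0, 2.889, 0.0, 9.997, 0.0, 0.0],
        [0.0, 0.0, 9.997, 0.0, 9.485, 0.0],
        [0.0, 0.0, 0.0, 9.485, 0.0, 9.482],
        [9.998, 0.0, 0.0, 0.0, 9.482, 0.0]
      ],
      "weights": [1, 1, 1, 1, 1, 1]
    },
    "sI": {
      "shifts_ppm": [3.34],
      "j_hz": [[0.0]],
      "weights": [6]
    },
    "Cr": {
      "shifts_ppm": [3.027, 3.913],
      "j_hz": [[0.0, 0.0], [0.0, 0.0]],
      "weights": [3, 2]
    },
    "PCr": {
      "shifts_ppm": [3.029, 3.93],
      "j_hz": [[0.0, 0.0], [0.0, 0.0]],
      "weights": [3, 2]
    },
    "NAA": {
      "shifts_ppm": [2.008, 4.3817, 2.6727, 2.4863],
      "j_hz": [
        [0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 3.861, 9.821],
        [0.0, 3.861, 0.0, -15.592],
        [0.0, 9.821, -15.592, 0.0]
      ],
      "weights": [3, 1, 1, 1]
    },
    "Lac": {
      "shifts_ppm": [4.0974, 1.3142, 1.3142, 1.3142],
      "j_hz": [
        [0.0, 6.933, 6.933, 6.933],
        [6.933, 0.0, 0.0, 0.0],
        [6.933, 0.0, 0.0, 0.0],
        [6.933, 0.0, 0.0, 0.0]
      ],
      "weights": [1, 1, 1, 1]
    },
    "Glu": {
      "shifts_ppm": [3.7433, 2.0375, 2.12, 2.3378, 2.352],
      "j_hz": [
        [0.0, 7.331, 4.651, 0.0, 0.0],
        [7.331, 0.0, -14.849, 6.413, 8.406],
        [4.651, -14.849, 0.0, 8.478, 6.875],
        [0.0, 6.413, 8.478, 0.0, -15.915],
        [0.0, 8.406, 6.875, -15.915, 0.0]
      ],
      "weights": [1, 1, 1, 1, 1]
    },
    "Gln": {
      "shifts_ppm": [3.753, 2.129, 2.109, 2.432, 2.454],
      "j_hz": [
        [0.0, 5.847, 6.5, 0.0, 0.0],
        [5.847, 0.0, -14.504, 9.165, 6.347],
        [6.5, -14.504, 0.0, 6.324, 9.209],
        [0.0, 9.165, 6.324, 0.0, -15.371],
        [0.0, 6.347, 9.209, -15.371, 0.0]
      ],
      "weights": [1, 1, 1, 1, 1]
    },
    "Asp": {
      "shifts_ppm": [3.8914, 2.8011, 2.6533],
      "j_hz": [
        [0.0, 3.647, 9.107],
        [3.647, 0.0, -17.426],
        [9.107, -17.426, 0.0]
      ],
      "weights": [1, 1, 1]
    },
    "GABA": {
      "shifts_ppm": [2.284, 2.284, 1.889, 1.889, 3.0128, 3.0128],
      "j_hz": [
        [0.0, 0.0, 7.3, 7.3, 0.0, 0.0],
        [0.0, 0.0, 7.3, 7.3, 0.0, 0.0],
        [7.3, 7.3, 0.0, 0.0, 7.0, 7.0],
        [7.3, 7.3, 0.0, 0.0, 7.0, 7.0],
        [0.0, 0.0, 7.0, 7.0, 0.0, 0.0],
        [0.0, 0.0, 7.0, 7.0, 0.0, 0.0]
      ],
      "weights": [1, 1, 1, 1, 1, 1]
    },
    "Tau": {
      "shifts_ppm": [3.4206, 3.4206, 3.2459, 3.2459],
      "j_hz": [
        [0.0, 0.0, 6.742, 6.403],
        [0.0, 0.0, 6.403, 6.742],
        [6.742, 6.403, 0.0, 0.0],
        [6.403, 6.742, 0.0, 0.0]
      ],
      "weights": [1, 1, 1, 1]
    },
    "Cho": {
      "shifts_ppm": [3.185, 4.054, 3.501],
      "j_hz": [
        [0.0, 0.0, 0.0],
        [0.0, 0.0, 5.77],
        [0.0, 5.77, 0.0]
      ],
      "weights": [9, 2, 2]
    },
    "GPC": {
      "shifts_ppm": [3.212, 4.312, 3.659],
      "j_hz": [
        [0.0, 0.0, 0.0],
        [0.0, 0.0, 5.77],
        [0.0, 5.77, 0.0]
      ],
      "weights": [9, 2, 2]
    },
    "PCho": {
      "shifts_ppm": [3.208, 4.2805, 3.641],
      "j_hz": [
        [0.0, 0.0, 0.0],
        [0.0, 0.0, 5.69],
        [0.0, 5.69, 0.0]
      ],
      "weights": [9, 2, 2]
    },
    "Asc": {
      "shifts_ppm": [4.492, 4.002, 3.741, 3.719],
      "j_hz": [
        [0.0, 2.07, 0.0, 0.0],
        [2.07, 0.0, 5.61, 7.27],
        [0.0, 5.61, 0.0, -11.5],
        [0.0, 7.27, -11.5, 0.0]
      ],
      "weights": [1, 1, 1, 1]
    },
    "PE": {
      "shifts_ppm": [3.9765, 3.9765, 3.216, 3.216],
      "j_hz": [
        [0.0, 0.0, 6.9, 6.9],
        [0.0, 0.0, 6.9, 6.9],
        [6.9, 6.9, 0.0, 0.0],
        [6.9, 6.9, 0.0, 0.0]
      ],
      "weights": [1, 1, 1, 1]
    },
    "EA": {
      "shifts_ppm": [3.8184, 3.8184, 3.1467, 3.1467],
      "j_hz": [
        [0.0, 0.0, 6.5, 6.5],
        [0.0, 0.0, 6.5, 6.5],
        [6.5, 6.5, 0.0, 0.0],
        [6.5, 6.5, 0.0, 0.0]
      ],
      "weights": [1, 1, 1, 1]
    }
  }
}
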