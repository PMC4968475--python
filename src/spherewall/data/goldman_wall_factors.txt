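# Goldman-model wall-correction factors for a sphere in linear shear near a plane wall.
# Computed with the spherewall wall-bounded Stokes solver, linear-profile mode, resolution 'fine'.
# Generated 2026-09-22 by scripts/build_goldman_table.py.
# Columns: eps=h/a, F_star = Fx/(6 pi mu a gammadot (a+h)), T_star = Tz/(4 pi mu a^3 gammadot),
# U_star = u/(gammadot (a+h)), W_star = omega/gammadot (free motion).
# eps F_star T_star U_star W_star
0.00500000 1.69654336 0.94384810 0.50637504 0.28362915
0.00800000 1.69435077 0.94413959 0.52593965 0.28688838
0.01380000 1.69013707 0.94468028 0.55674460 0.29641447
0.02200000 1.68424228 0.94540601 0.59053925 0.30981375
0.03500000 1.67507002 0.94650174 0.63046714 0.32718272
0.06000000 1.65805584 0.94851191 0.68356621 0.35113794
0.10000000 1.63246874 0.95156060 0.73920179 0.37659093
0.15000000 1.60300441 0.95503808 0.78566016 0.39798089
0.23333333 1.55930097 0.96019197 0.83637044 0.42145724
0.35000000 1.50737143 0.96624677 0.88030396 0.44180013
0.55000000 1.43702032 0.97427879 0.92293931 0.46200496
0.90000000 1.35050006 0.98338996 0.95825535 0.47904826
1.50000000 1.26018432 0.99127474 0.98133232 0.49038656
2.50000000 1.18067415 0.99620717 0.99302405 0.49619897
4.50000000 1.11118140 0.99869863 0.99816175 0.49876707
10.00000000 1.05355644 0.99953773 0.99976737 0.49957135
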