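{
 "version": 1,
 "sites": [
  {
   "kind": "donor",
   "center": [
    -3.028867525661177,
    -0.5934891829191183,
    0.018938586478291906
   ],
   "tolerance": 1.5
  },
  {
   "kind": "donor",
   "center": [
    3.4331260554577203,
    -0.22965052970197608,
    -0.06020984767277157
   ],
   "tolerance": 1.5
  },
  {
   "kind": "acceptor",
   "center": [
    -2.5040712591045966,
    1.6473677325165457,
    -0.1868716962729988
   ],
   "tolerance": 1.5
  },
  {
   "kind": "hydrophobic",
   "center": [
    0.7067467972210076,
    0.09047731757826898,
    -0.06949550341937595
   ],
   "tolerance": 3.0
  }
 ],
 "excluded_volumes": [
  {
   "center": [
    -9.74582576751709,
    4.730731010437012,
    -2.0391156673431396
   ],
   "radius": 1.52,
   "source_atom": "O"
  },
  {
   "center": [
    -10.621118545532227,
    3.9304699897766113,
    -2.365222454071045
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    -11.058611869812012,
    2.5064268112182617,
    -2.667051076889038
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    -10.28076457977295,
    1.7114195823669434,
    -1.7212615013122559
   ],
   "radius": 1.55,
   "source_atom": "N"
  },
  {
   "center": [
    -7.433772563934326,
    2.1123194694519043,
    -1.8192776441574097
   ],
   "radius": 1.52,
   "source_atom": "O"
  },
  {
   "center": [
    -8.309064865112305,
    1.3120583295822144,
    -2.1453843116760254
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    -8.74655818939209,
    -0.11198489367961884,
    -2.4472131729125977
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    -7.9687113761901855,
    -0.9069921374320984,
    -1.5014234781265259
   ],
   "radius": 1.55,
   "source_atom": "N"
  },
  {
   "center": [
    -5.997011661529541,
    -1.3063534498214722,
    -1.9255462884902954
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    -6.434504508972168,
    -2.7303967475891113,
    -2.227375030517578
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    -5.656658172607422,
    -3.5254039764404297,
    -1.2815853357315063
   ],
   "radius": 1.55,
   "source_atom": "N"
  },
  {
   "center": [
    -3.684957981109619,
    -3.924765110015869,
    -1.7057082653045654
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    -4.122451305389404,
    -5.348808288574219,
    -2.0075368881225586
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    -3.3446044921875,
    -6.143815517425537,
    -1.0617473125457764
   ],
   "radius": 1.55,
   "source_atom": "N"
  },
  {
   "center": [
    -0.49761226773262024,
    -5.742915630340576,
    -1.1597634553909302
   ],
   "radius": 1.52,
   "source_atom": "O"
  },
  {
   "center": [
    -1.3729045391082764,
    -6.543177127838135,
    -1.485870122909546
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    -1.810397744178772,
    -7.967220306396484,
    -1.7876988649368286
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    -1.0325511693954468,
    -8.762227058410645,
    -0.8419091701507568
   ],
   "radius": 1.55,
   "source_atom": "N"
  },
  {
   "center": [
    0.6780645251274109,
    -0.26931333541870117,
    -4.053178310394287
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    1.3049461841583252,
    -1.0971907377243042,
    -5.190384864807129
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    0.033937204629182816,
    0.3422330915927887,
    -5.31123685836792
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    0.6670218706130981,
    -0.4078327417373657,
    -5.586895942687988
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    1.6314784288406372,
    -1.5000845193862915,
    -5.495192050933838
   ],
   "radius": 1.55,
   "source_atom": "N"
  },
  {
   "center": [
    1.3693150281906128,
    -1.3085873126983643,
    -6.589804649353027
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    1.3604952096939087,
    -1.4192228317260742,
    -7.814786911010742
   ],
   "radius": 1.52,
   "source_atom": "O"
  },
  {
   "center": [
    0.7411655187606812,
    0.522226095199585,
    4.710923671722412
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    0.7522081732749939,
    0.6607455015182495,
    6.2446417808532715
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    1.0551050901412964,
    0.4623692035675049,
    7.741471767425537
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    2.019561767578125,
    -0.6298825740814209,
    7.8331756591796875
   ],
   "radius": 1.55,
   "source_atom": "N"
  },
  {
   "center": [
    1.0660043954849243,
    0.5990896224975586,
    9.255270957946777
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    1.0571845769882202,
    0.48845401406288147,
    8.030288696289062
   ],
   "radius": 1.52,
   "source_atom": "O"
  },
  {
   "center": [
    3.247939109802246,
    -3.1688318252563477,
    -3.6984410285949707
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    3.959473133087158,
    -4.0814385414123535,
    -4.714545726776123
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    4.759079456329346,
    -5.079078197479248,
    -5.573000431060791
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    5.723536014556885,
    -6.171329975128174,
    -5.481296539306641
   ],
   "radius": 1.55,
   "source_atom": "N"
  },
  {
   "center": [
    5.461372375488281,
    -5.979832649230957,
    -6.57590913772583
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    5.452552795410156,
    -6.090468406677246,
    -7.800891399383545
   ],
   "radius": 1.52,
   "source_atom": "O"
  },
  {
   "center": [
    -1.8902194499969482,
    2.650157928466797,
    -4.186995029449463
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    -2.617370128631592,
    3.366868257522583,
    -5.339894771575928
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    -3.2098019123077393,
    3.9140753746032715,
    -6.651835918426514
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    -2.2453453540802,
    2.821823835372925,
    -6.560132026672363
   ],
   "radius": 1.55,
   "source_atom": "N"
  },
  {
   "center": [
    -3.92750883102417,
    4.621478080749512,
    -7.7897629737854
   ],
   "radius": 1.7,
   "source_atom": "C"
  },
  {
   "center": [
    -3.936328649520874,
    4.510842323303223,
    -9.014745712280273
   ],
   "radius": 1.52,
   "source_atom": "O"
  }
 ],
 "min_match_sites": 3,
 "mandatory_sites": [],
 "prefer_more_sites": false
}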