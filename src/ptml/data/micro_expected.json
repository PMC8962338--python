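{
 "gti": {
  "M1": {
   "X(P)1": 1.0,
   "SM(Ato)1": 24.022,
   "Ne(P)1": 0.0
  },
  "M2": {
   "X(P)1": 1.414213562373095,
   "SM(Ato)1": 36.033,
   "Ne(P)1": 0.5
  },
  "M3": {
   "X(P)1": 1.914213562373095,
   "SM(Ato)1": 48.044,
   "Ne(P)1": 0.4714045207910316
  },
  "M4": {
   "X(P)1": 1.7320508075688776,
   "SM(Ato)1": 48.044,
   "Ne(P)1": 0.5
  },
  "M5": {
   "X(P)1": 1.414213562373095,
   "SM(Ato)1": 40.021,
   "Ne(P)1": 0.5
  },
  "M6": {
   "X(P)1": 1.414213562373095,
   "SM(Ato)1": 40.021,
   "Ne(P)1": 0.5
  },
  "M7": {
   "X(P)1": 1.5,
   "SM(Ato)1": 36.033,
   "Ne(P)1": 0.5
  },
  "M8": {
   "X(P)1": 1.414213562373095,
   "SM(Ato)1": 38.028999999999996,
   "Ne(P)1": 0.5
  }
 },
 "labels": {
  "M1": 1,
  "M2": 1,
  "M3": -1,
  "M4": -1,
  "M5": 1,
  "M6": 1,
  "M7": -1,
  "M8": -1
 },
 "stats": {
  "std": {
   "X(P)1": 0.2672645610942616,
   "SM(Ato)1": 7.6361745366100315,
   "Ne(P)1": 0.17561770731220644
  },
  "avg": {
   "ma": {
    "IC50(nM)p": {
     "X(P)1": 1.3106601717798212,
     "SM(Ato)1": 35.024249999999995,
     "Ne(P)1": 0.375
    }
   },
   "tg": {
    "Caspase-1": {
     "X(P)1": 1.2071067811865475,
     "SM(Ato)1": 30.0275,
     "Ne(P)1": 0.25
    },
    "TNF-alpha": {
     "X(P)1": 1.414213562373095,
     "SM(Ato)1": 40.021,
     "Ne(P)1": 0.5
    }
   },
   "ei": {
    "B (single protein format)": {
     "X(P)1": 1.3106601717798212,
     "SM(Ato)1": 35.024249999999995,
     "Ne(P)1": 0.375
    }
   }
  },
  "ps": {
   "ma": {
    "IC50(nM)p": 0.5
   },
   "tg": {
    "Caspase-1": 0.5,
    "TNF-alpha": 0.5
   },
   "ei": {
    "B (single protein format)": 0.5
   }
  }
 },
 "deviations": {
  "M1": {
   "D(X(P)1)ma": -2.324738981538629,
   "D(SM(Ato)1)tg": -1.5729079976388427,
   "D(Ne(P)1)ei": -4.270639968364231
  },
  "M2": {
   "D(X(P)1)ma": 0.7749129938462096,
   "D(SM(Ato)1)tg": 1.5729079976388427,
   "D(Ne(P)1)ei": 1.42354665612141
  },
  "M3": {
   "D(X(P)1)ma": 4.516523912651527,
   "D(SM(Ato)1)tg": 4.7187239929165266,
   "D(Ne(P)1)ei": 1.0978906656564802
  },
  "M4": {
   "D(X(P)1)ma": 3.1533596079012964,
   "D(SM(Ato)1)tg": 4.7187239929165266,
   "D(Ne(P)1)ei": 1.42354665612141
  },
  "M5": {
   "D(X(P)1)ma": 0.7749129938462096,
   "D(SM(Ato)1)tg": 0.0,
   "D(Ne(P)1)ei": 1.42354665612141
  },
  "M6": {
   "D(X(P)1)ma": 0.7749129938462096,
   "D(SM(Ato)1)tg": 0.0,
   "D(Ne(P)1)ei": 1.42354665612141
  },
  "M7": {
   "D(X(P)1)ma": 1.4168719372666883,
   "D(SM(Ato)1)tg": -1.0445020555463662,
   "D(Ne(P)1)ei": 1.42354665612141
  },
  "M8": {
   "D(X(P)1)ma": 0.7749129938462096,
   "D(SM(Ato)1)tg": -0.5217272052779254,
   "D(Ne(P)1)ei": 1.42354665612141
  }
 }
}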