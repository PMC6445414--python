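predator,prey,fraction,trace
Killer whale,Leopard seal,0.03,0
Killer whale,Weddell seal,0.465,0
Killer whale,Crabeater seal,0.365,0
Killer whale,S elephant seal,0.01,0
Killer whale,Blue whale,0.01,0
Killer whale,Fin whale,0.01,0
Killer whale,Minke whale,0.01,0
Killer whale,Humpback whale,0.01,0
Killer whale,Emperor penguin,,1
Killer whale,Gentoo penguin,,1
Killer whale,Chinstrap penguin,0.02,0
Killer whale,Adelie penguin,,1
Killer whale,Myctophids,0.03,0
Killer whale,On-shelf fish,0.02,0
Killer whale,N. rossii,,1
Killer whale,G. gibberifrons,0.01,0
Leopard seal,Antarctic fur seal,,1
Leopard seal,Gentoo penguin,,1
Leopard seal,Chinstrap penguin,0.03,0
Leopard seal,Cephalopods,0.078,0
Leopard seal,Myctophids,0.04,0
Leopard seal,G. gibberifrons,0.15,0
Leopard seal,Large krill,0.70,0
Weddell seal,Cephalopods,0.08,0
Weddell seal,Myctophids,0.05,0
Weddell seal,On-shelf fish,0.60,0
Weddell seal,G. gibberifrons,0.22,0
Weddell seal,Benthic invertebrates,0.05,0
Crabeater seal,Cephalopods,0.075,0
Crabeater seal,Myctophids,0.075,0
Crabeater seal,On-shelf fish,0.07,0
Crabeater seal,Large krill,0.78,0
Antarctic fur seal,Gentoo penguin,0.01,0
Antarctic fur seal,Chinstrap penguin,0.03,0
Antarctic fur seal,Adelie penguin,,1
Antarctic fur seal,Macaroni penguin,,1
Antarctic fur seal,Cephalopods,0.054,0
Antarctic fur seal,Myctophids,0.20,0
Antarctic fur seal,On-shelf fish,0.20,0
Antarctic fur seal,Large krill,0.50,0
S elephant seal,Cephalopods,0.60,0
S elephant seal,Myctophids,0.10,0
S elephant seal,On-shelf fish,0.14,0
S elephant seal,N. rossii,0.10,0
S elephant seal,G. gibberifrons,0.06,0
Sperm whale,Cephalopods,0.85,0
Sperm whale,Myctophids,,1
Sperm whale,On-shelf fish,0.045,0
Sperm whale,Benthic invertebrates,0.10,0
Blue whale,Large krill,0.61,0
Blue whale,Other euphausiids,0.20,0
Blue whale,Macrozooplankton,0.19,0
Fin whale,Myctophids,0.015,0
Fin whale,On-shelf fish,0.015,0
Fin whale,Large krill,0.71,0
Fin whale,Other euphausiids,0.12,0
Fin whale,Mesozooplankton,0.01,0
Fin whale,Macrozooplankton,0.13,0
Minke whale,Myctophids,0.01,0
Minke whale,On-shelf fish,0.01,0
Minke whale,Large krill,0.76,0
Minke whale,Other euphausiids,0.11,0
Minke whale,Macrozooplankton,0.11,0
Humpback whale,Cephalopods,0.06,0
Humpback whale,Myctophids,0.04,0
Humpback whale,On-shelf fish,0.04,0
Humpback whale,Large krill,0.76,0
Humpback whale,Mesozooplankton,0.015,0
Humpback whale,Macrozooplankton,0.085,0
Emperor penguin,Cephalopods,0.10,0
Emperor penguin,On-shelf fish,0.38,0
Emperor penguin,Large krill,0.52,0
Gentoo penguin,Myctophids,0.10,0
Gentoo penguin,On-shelf fish,0.10,0
Gentoo penguin,Large krill,0.80,0
Chinstrap penguin,Myctophids,0.0225,0
Chinstrap penguin,On-shelf fish,0.0225,0
Chinstrap penguin,Large krill,0.95,0
Chinstrap penguin,Macrozooplankton,,1
Adelie penguin,Myctophids,0.0125,0
Adelie penguin,C. gunnari,,1
Adelie penguin,G. gibberifrons,0.0125,0
Adelie penguin,Large krill,0.962,0
Adelie penguin,Macrozooplankton,0.0125,0
Macaroni penguin,Cephalopods,0.01,0
Macaroni penguin,Myctophids,0.10,0
Macaroni penguin,On-shelf fish,0.12,0
Macaroni penguin,Large krill,0.34,0
Macaroni penguin,Other euphausiids,0.35,0
Macaroni penguin,Mesozooplankton,0.08,0
Flying birds,Cephalopods,0.46,0
Flying birds,Myctophids,0.043,0
Flying birds,On-shelf fish,0.087,0
Flying birds,Large krill,0.30,0
Flying birds,Mesozooplankton,,1
Flying birds,Macrozooplankton,0.105,0
Cephalopods,Myctophids,0.02,0
Cephalopods,On-shelf fish,0.02,0
Cephalopods,Benthic invertebrates,0.21,0
Cephalopods,Large krill,0.40,0
Cephalopods,Other euphausiids,0.15,0
Cephalopods,Macrozooplankton,0.20,0
Myctophids,Large krill,0.25,0
Myctophids,Other euphausiids,0.35,0
Myctophids,Mesozooplankton,0.05,0
Myctophids,Macrozooplankton,0.35,0
On-shelf fish,Cephalopods,0.055,0
On-shelf fish,Myctophids,0.02,0
On-shelf fish,C. gunnari,0.015,0
On-shelf fish,Salps,0.01,0
On-shelf fish,Benthic invertebrates,0.20,0
On-shelf fish,Large krill,0.25,0
On-shelf fish,Other euphausiids,0.135,0
On-shelf fish,Mesozooplankton,0.085,0
On-shelf fish,Macrozooplankton,0.23,0
N. rossii,Myctophids,0.10,0
N. rossii,Salps,0.02,0
N. rossii,Benthic invertebrates,0.02,0
N. rossii,Large krill,0.60,0
N. rossii,Other euphausiids,0.20,0
N. rossii,Ice algae,0.06,0
C. gunnari,Myctophids,0.01,0
C. gunnari,Large krill,0.90,0
C. gunnari,Other euphausiids,0.08,0
C. gunnari,Macrozooplankton,0.01,0
G. gibberifrons,Cephalopods,0.01,0
G. gibberifrons,Myctophids,0.02,0
G. gibberifrons,Salps,0.17,0
G. gibberifrons,Benthic invertebrates,0.59,0
G. gibberifrons,Large krill,0.09,0
G. gibberifrons,Macrozooplankton,0.02,0
G. gibberifrons,Ice algae,0.10,0
Salps,Small krill,,1
Salps,Microzooplankton,0.104,0
Salps,Mesozooplankton,0.03,0
Salps,Small phytoplankton,0.415,0
Salps,Large phytoplankton,0.45,0
Benthic invertebrates,Detritus,1.0,0
Large krill,Mesozooplankton,0.10,0
Large krill,Large phytoplankton,0.50,0
Large krill,Ice algae,0.10,0
Large krill,Detritus,0.30,0
Small krill,Microzooplankton,0.10,0
Small krill,Small phytoplankton,0.275,0
Small krill,Large phytoplankton,0.275,0
Small krill,Ice algae,0.25,0
Small krill,Detritus,0.10,0
Other euphausiids,Mesozooplankton,0.20,0
Other euphausiids,Large phytoplankton,0.60,0
Other euphausiids,Detritus,0.20,0
Microzooplankton,Small phytoplankton,0.60,0
Microzooplankton,Large phytoplankton,0.25,0
Microzooplankton,Detritus,0.15,0
Mesozooplankton,Microzooplankton,0.03,0
Mesozooplankton,Small phytoplankton,0.24,0
Mesozooplankton,Large phytoplankton,0.66,0
Mesozooplankton,Detritus,0.07,0
Macrozooplankton,Large krill,0.01,0
Macrozooplankton,Small krill,0.02,0
Macrozooplankton,Other euphausiids,0.01,0
Macrozooplankton,Mesozooplankton,0.50,0
Macrozooplankton,Small phytoplankton,0.10,0
Macrozooplankton,Large phytoplankton,0.21,0
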