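name,role,biomass,pb,qb,pq,ee,ba_rate,landings,unassim
Killer whale,consumer,0.75,0.02,1.08,,,0,0,0.2
Leopard seal,consumer,0.84,0.27,15.17,,,0,0,0.2
Weddell seal,consumer,8.12,0.08,4.60,,,0,0,0.2
Crabeater seal,consumer,109.78,0.10,5.95,,,0,0,0.2
Antarctic fur seal,consumer,0.10,0.17,9.66,,,0,0,0.2
S elephant seal,consumer,0.10,0.21,12.07,,,0,0,0.2
Sperm whale,consumer,2.84,0.29,16.67,,,0,0,0.2
Blue whale,consumer,0.72,0.04,2.53,,,0,0,0.2
Fin whale,consumer,4.28,0.03,2.55,,,0.029,0,0.2
Minke whale,consumer,4.73,0.10,5.65,,,0,0,0.2
Humpback whale,consumer,8.12,0.04,2.38,,,0.039,0,0.2
Emperor penguin,consumer,0.01,0.19,13.89,,,0,0,0.2
Gentoo penguin,consumer,0.12,0.22,15.28,,,0,0,0.2
Chinstrap penguin,consumer,2.14,0.22,15.28,,,0,0,0.2
Adelie penguin,consumer,0.58,0.12,36.62,,,0,0,0.2
Macaroni penguin,consumer,0.01,0.11,7.64,,,0,0,0.2
Flying birds,consumer,0.40,0.09,4.89,,,0,0,0.2
Cephalopods,consumer,249.00,3.15,30.29,,,0,0,0.2
Myctophids,consumer,327.00,1.10,10.58,,,0,0,0.2
On-shelf fish,consumer,525.00,0.46,4.42,,,0,0,0.2
N. rossii,consumer,13.80,0.29,2.79,,,0,0,0.2
C. gunnari,consumer,90.00,0.48,4.62,,,0,0,0.2
G. gibberifrons,consumer,120.00,0.46,4.42,,,0,0,0.2
Salps,consumer,16000.00,3.00,12.25,,,0,0,0.2
Benthic invertebrates,consumer,8553.75,0.50,2.19,,,0,0,0.2
Large krill,consumer,8126.00,0.8,3.57,,,0,8.1,0.2
Small krill,consumer,,0.8,6.51,,,0,0,0.2
Other euphausiids,consumer,14800.0,1.5,6.70,,,0,0,0.2
Microzooplankton,consumer,2500.00,55,275.00,,,0,0,0.2
Mesozooplankton,consumer,13000.00,4.81,19.63,,,0,0,0.2
Macrozooplankton,consumer,3500.00,2.5,8.93,,,0,0,0.2
Small phytoplankton,producer,,75,,,0.5,0,0,0
Large phytoplankton,producer,,75,,,0.5,0,0,0
Ice algae,producer,,50,,,0.5,0,0,0
Detritus,detritus,577.00,,,,,0,0,0
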