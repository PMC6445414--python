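group,ae,pe,pq
Killer whale,0.8,0.023148,0.018519
Leopard seal,0.8,0.022248,0.017798
Weddell seal,0.8,0.021739,0.017391
Crabeater seal,0.8,0.021008,0.016807
Antarctic fur seal,0.8,0.021998,0.017598
S elephant seal,0.8,0.021748,0.017399
Sperm whale,0.8,0.021746,0.017397
Blue whale,0.8,0.019763,0.01581
Fin whale,0.8,0.014706,0.011765
Minke whale,0.8,0.022124,0.017699
Humpback whale,0.8,0.021008,0.016807
Emperor penguin,0.8,0.017099,0.013679
Gentoo penguin,0.8,0.017997,0.014398
Chinstrap penguin,0.8,0.017997,0.014398
Adelie penguin,0.8,0.004096,0.003277
Macaroni penguin,0.8,0.017997,0.014398
Flying birds,0.8,0.023006,0.018405
Cephalopods,0.8,0.129993,0.103995
Myctophids,0.8,0.129962,0.10397
On-shelf fish,0.8,0.13009,0.104072
N. rossii,0.8,0.129928,0.103943
C. gunnari,0.8,0.12987,0.103896
G. gibberifrons,0.8,0.13009,0.104072
Salps,0.8,0.306122,0.244898
Benthic invertebrates,0.8,0.285388,0.228311
Large krill,0.8,0.280112,0.22409
Small krill,0.8,0.15361,0.122888
Other euphausiids,0.8,0.279851,0.223881
Microzooplankton,0.8,0.25,0.2
Mesozooplankton,0.8,0.306291,0.245033
Macrozooplankton,0.8,0.349944,0.279955
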