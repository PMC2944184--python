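(((t001:8.4853697722471466,t110:8.4853697722471466):2.7762079083899107,t022:11.261577680637057):4.9384223193629397,((((t002:0.35365845527438122,t120:0.35365845527438122):6.5241642280095409,(t067:6.3896378330306547,(t033:4.4160621882573556,((t056:0.87167507561329083,t107:0.87167507561329083):1.1380775951566973,t084:2.0097526707699882):2.4063095174873679):1.9735756447732986):0.48818485025326819):3.7459899068619671,((t010:0.83723434972205324,t108:0.83723434972205324):3.5192090947942636,(t058:1.5580443734849829,t092:1.5580443734849829):2.7983990710313336):6.2673691456295728):4.8475537410215059,(((((t003:2.2343816590620031,t079:2.2343816590620031):1.3018353792962143,t064:3.5362170383582172):0.91384081446764232,t054:4.4500578528258599):6.6259535542084826,(((t008:4.7048623303364536,(t051:4.5737372712449416,(t053:3.6391351306973081,(t062:0.11199953541930724,t122:0.11199953541930724):3.5271355952780006):0.93460214054763358):0.13112505909151184):4.479607636006758,(((t018:5.0021363531006591,t049:5.0021363531006591):1.5003316139772649,(((t030:1.1906432334812054,(t097:0.72705530098552384,t112:0.72705530098552384):0.46358793249568159):0.9291031822952166,t082:2.1197464157764219):4.2328679252472439,((t035:1.158506555164909,t099:1.158506555164909):3.4739828894151663,t052:4.6324894445800755):1.7201248964435909):0.14985362605425817):1.4028288794618258,((((t046:2.8324053089248333,t073:2.8324053089248333):3.895471423770374,(t028:5.1688202565388677,t047:5.1688202565388677):1.5590564761563395):0.15190657199964577,(((t025:4.7214868935195344,t050:4.7214868935195344):1.2375117278265928,(t041:5.6030135229970872,(t043:0.32141905114716146,t121:0.32141905114716146):5.2815944718499255):0.35598509834904046):0.80398997600533517,(t109:6.3308080962985436,(t037:2.1287013923329936,t081:2.1287013923329936):4.2021067039655504):0.43218050105291889):0.11679470734339061):0.30081743667539895,(((t019:6.2498542936443924,(t078:2.0151551735416002,t083:2.0151551735416002):4.2346991201027917):0.30259794304695853,((t029:4.0866327826700459,(t059:1.8302471065297672,(t089:1.1665933939721189,t098:1.1665933939721189):0.66365371255764816):2.2563856761402792):2.4150476292615921,(((t031:4.4248307098342714,(t055:2.8090371421564861,(t075:1.768535710609263,((t090:0.46600918034952937,t116:0.46600918034952937):0.55375819185139763,t101:1.0197673722009271):0.7487683384083359):1.0405014315472234):1.6157935676777853):1.0310890556740262,t045:5.4559197655082974):0.9131964145243332,(t034:4.0199411569311607,((t060:2.8620351719737869,t072:2.8620351719737869):0.041203861812879716,t071:2.9032390337866665):1.1167021231444947):2.3491750231014699):0.13256423189900743):0.050771824759712092):0.46996687544095311,t065:7.0224191121323036):0.15818162923794857):0.7246961051694979):1.279173119803461):0.95096714712238373,(t012:5.1621418969079675,(t048:3.3893369875718173,(t066:3.0315747923218295,(t114:0.75017375117353557,t111:0.75017375117353557):2.2814010411482939):0.35776219524998776):1.7728049093361504):4.9732952165576272):0.94057429356874678):2.1634594774105071,(((t004:2.9384910523226706,((t106:1.0183186025979081,(t102:0.43566004910124045,t118:0.43566004910124045):0.58265855349666762):0.86918375186432817,t087:1.8875023544622362):1.0509886978604346):7.886633908942704,t076:10.825124961265375):0.89753364005596858,(t005:11.206275965150965,((t007:3.5652052623004766,(t063:0.39986609815703172,t119:0.39986609815703172):3.165339164143445):4.6633910009863424,(t016:7.1749551916976193,(((((t020:0.51771646983904396,t115:0.51771646983904396):0.48547057293359663,t103:1.0031870427726406):0.83601958552338718,t094:1.839206628296028):4.595155109389407,((t032:2.559054477751185,(t105:1.3472927441339846,t095:1.3472927441339846):1.2117617336172006):3.4413523303879479,((t040:3.6655467963401853,t061:3.6655467963401853):1.835086967334953,t044:5.5006337636751388):0.49977304446399451):0.43395492954630149):0.72202730097015677,t096:7.1563890386555915):0.018566153042027685):1.0536410715892):2.9776797018641465):0.51638263617037683):1.5168122831235062):2.2318954467225467):0.72863366883260183);
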